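"""Codon-specific linear-model enrichment scoring and perturbation profiles.

The central statistic of the screen.  For every codon identity (the
four programmed AKEL codons and every observed non-programmed codon) a
linear model of selected-sample counts against control-sample counts is
fitted across ORF positions.  Because library coverage varies smoothly
along the sequence, positions act as replicates of the codon-specific
count relationship; variants enriched by the reverse-Y2H selection stand
out as deviations from the fitted line, summarized by the mean absolute
error (MAE) per codon, while the enrichment of one variant is

    score = observed selected count / count expected from the model.

High-confidence calls require at least ``read_cutoff`` (default 50)
selected reads and enrichment above twofold variation of the linear
model, implemented as ``observed > expected + 2 x residual_scale`` with
``residual_scale`` the median absolute residual (a pure ``score >= 2``
reading is available via ``confidence_mode="ratio"``).

Per-position scores (default: maximum over the position's programmed
codons; missing stays missing, never zero) are normalized to Z-scores
per interaction sample and combined across biological replicates by
position-wise means; contiguous stretches of elevated smoothed Z form
hotspot regions.

Usage follows the model/results convention::

    model = EnrichmentModel(control_counts, selected_counts, catalog=cat)
    res = model.fit()
    print(res.summary())
    profile = res.zscore_profile("KDM1A-rep1")
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .calling import SampleCounts
from .isoforms import IsoformMap, MapStatus

__all__ = [
    "CodonModelFit", "EnrichmentModel", "EnrichmentResults",
    "PerturbationProfile", "enrichment_score", "combine_replicates",
    "detect_hotspots", "Hotspot", "plot_profile",
]


def enrichment_score(observed: float, expected: float) -> float:
    """Observed / expected count ratio for one variant."""
    if expected <= 0:
        raise ValueError("enrichment score undefined for expected <= 0")
    return observed / expected


@dataclass
class CodonModelFit:
    """Least-squares line through (control, selected) counts of one codon."""

    codon: str
    slope: float
    intercept: float
    residuals: pd.Series          # indexed by codon position
    mae: float
    residual_scale: float         # median absolute residual
    n_positions: int
    valid: bool

    def predict(self, control_count: float) -> float:
        return self.intercept + self.slope * control_count


class EnrichmentModel:
    """Codon-specific linear models of selected vs control counts.

    Parameters
    ----------
    control, selected : SampleCounts or DataFrame
        Codon-level counts (the control is the combined no-selection
        baseline, pooling all control sequencing runs).  DataFrames need
        columns ``codon_index``, ``codon``, ``count``.
    catalog : DataFrame, optional
        Programmed catalog; marks records as programmed and scopes
        position scores to programmed codons.
    min_positions : int
        Minimum positions carrying a codon in the control for a fit.
    read_cutoff : int
        Hard high-confidence cutoff on the observed selected count.
    confidence_mode : "residual" or "ratio"
        Reading of "enrichment above twofold variation of the linear
        model": ``observed > expected + 2*residual_scale`` (default) or
        ``score >= 2``.
    position_agg : "max" or "mean"
        How the (up to four) programmed codon scores collapse into one
        score per position.
    """

    def __init__(
        self,
        control,
        selected,
        catalog: Optional[pd.DataFrame] = None,
        min_positions: int = 3,
        read_cutoff: int = 50,
        confidence_mode: Literal["residual", "ratio"] = "residual",
        position_agg: Literal["max", "mean"] = "max",
    ):
        self.control = self._as_frame(control)
        self.selected = self._as_frame(selected)
        self.catalog = catalog
        self.min_positions = int(min_positions)
        self.read_cutoff = int(read_cutoff)
        if confidence_mode not in ("residual", "ratio"):
            raise ValueError(f"unknown confidence_mode {confidence_mode!r}")
        if position_agg not in ("max", "mean"):
            raise ValueError(f"unknown position_agg {position_agg!r}")
        self.confidence_mode = confidence_mode
        self.position_agg = position_agg
        self.n_codons = int(max(self.control["codon_index"].max(),
                                self.selected["codon_index"].max()))
        if isinstance(control, SampleCounts):
            self.n_codons = max(self.n_codons, control.n_codons)

    @staticmethod
    def _as_frame(counts) -> pd.DataFrame:
        if isinstance(counts, SampleCounts):
            return counts.to_frame()
        df = pd.DataFrame(counts)
        missing = {"codon_index", "codon", "count"} - set(df.columns)
        if missing:
            raise ValueError(f"counts frame lacks columns {sorted(missing)}")
        return df

    # -- fitting ---------------------------------------------------------------

    def fit(self) -> "EnrichmentResults":
        ctrl = self.control.set_index(["codon_index", "codon"])["count"]
        sel = self.selected.set_index(["codon_index", "codon"])["count"]
        programmed_set: set[tuple[int, str]] = set()
        if self.catalog is not None:
            programmed_set = set(zip(self.catalog["codon_index"].astype(int),
                                     self.catalog["mut_codon"]))
        codons = sorted(set(self.control["codon"]) | set(self.selected["codon"]))
        fits: dict[str, CodonModelFit] = {}
        for codon in codons:
            c = ctrl.xs(codon, level="codon") if codon in ctrl.index.get_level_values(1) else pd.Series(dtype=float)
            s = sel.xs(codon, level="codon") if codon in sel.index.get_level_values(1) else pd.Series(dtype=float)
            both = c.index.intersection(s.index)
            if len(c) < self.min_positions or len(both) < self.min_positions:
                fits[codon] = CodonModelFit(codon, np.nan, np.nan,
                                            pd.Series(dtype=float), np.nan,
                                            np.nan, len(both), False)
                continue
            x = c.loc[both].to_numpy(float)
            y = s.loc[both].to_numpy(float)
            # has_constant="add": a codon with constant control counts must
            # still get an intercept column (pinv handles the collinearity)
            ols = sm.OLS(y, sm.add_constant(x, has_constant="add")).fit()
            resid = pd.Series(ols.resid, index=both)
            fits[codon] = CodonModelFit(
                codon,
                slope=float(ols.params[1]),
                intercept=float(ols.params[0]),
                residuals=resid,
                mae=float(np.abs(resid).mean()),
                residual_scale=float(np.median(np.abs(resid))),
                n_positions=len(both),
                valid=True,
            )

        records = self._build_records(ctrl, sel, fits, programmed_set)
        return EnrichmentResults(self, fits, records)

    def _build_records(self, ctrl, sel, fits, programmed_set) -> pd.DataFrame:
        rows = []
        sel_d = sel.to_dict()
        for (pos, codon), c_count in ctrl.items():
            f = fits.get(codon)
            if f is None or not f.valid:
                continue
            expected = f.predict(float(c_count))
            observed = float(sel_d.get((pos, codon), 0.0))
            if expected <= 0:
                rows.append((pos, codon, observed, expected, np.nan, False,
                             (pos, codon) in programmed_set, "expected<=0"))
                continue
            score = observed / expected
            if self.confidence_mode == "residual":
                enriched = observed > expected + 2.0 * f.residual_scale
            else:
                enriched = score >= 2.0
            hc = (observed >= self.read_cutoff) and enriched
            rows.append((pos, codon, observed, expected, score, hc,
                         (pos, codon) in programmed_set, ""))
        return pd.DataFrame(
            rows, columns=["codon_index", "codon", "observed", "expected",
                           "score", "high_confidence", "programmed", "excluded"],
        )


@dataclass
class PerturbationProfile:
    """Per-position enrichment/Z-score track for one interaction sample."""

    interaction: str
    scores: pd.Series             # raw per-position scores, NaN = missing
    z: pd.Series                  # Z over scored positions
    replicates: tuple[str, ...] = ()

    @property
    def positions(self) -> pd.Index:
        return self.scores.index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.scores.index,
                             "score": self.scores.to_numpy(),
                             "z": self.z.to_numpy()})

    def to_tsv(self, path, header_lines: Iterable[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write(f"# interaction={self.interaction} "
                     f"replicates={','.join(self.replicates) or '-'}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


def _zscore(scores: pd.Series) -> pd.Series:
    vals = scores.dropna()
    if len(vals) == 0:
        return scores.copy()
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    if sd == 0.0:
        z = scores * 0.0
    else:
        z = (scores - float(vals.mean())) / sd
    return z


class EnrichmentResults:
    """Fitted enrichment scores, per-codon models and profile constructors."""

    def __init__(self, model: EnrichmentModel, fits: dict[str, CodonModelFit],
                 records: pd.DataFrame):
        self.model = model
        self.fits = fits
        self.records = records

    # -- tables ----------------------------------------------------------------

    def fit_table(self) -> pd.DataFrame:
        rows = [(f.codon, f.slope, f.intercept, f.mae, f.residual_scale,
                 f.n_positions, f.valid) for f in self.fits.values()]
        return pd.DataFrame(rows, columns=["codon", "slope", "intercept", "mae",
                                           "residual_scale", "n_positions",
                                           "valid"]).sort_values("codon",
                                                                 ignore_index=True)

    def mae_by_class(self) -> pd.DataFrame:
        """MAE per codon, split into programmed vs other codons."""
        programmed = set()
        if self.model.catalog is not None:
            programmed = set(self.model.catalog["mut_codon"].unique())
        tab = self.fit_table()
        tab = tab[tab["valid"]].copy()
        tab["programmed"] = tab["codon"].isin(programmed)
        return tab[["codon", "mae", "n_positions", "programmed"]]

    # -- scores ----------------------------------------------------------------

    def position_scores(self, require_high_confidence: bool = False) -> pd.Series:
        """One score per ORF position (programmed codons only when a catalog
        is present); positions with no scored codon are missing, not zero."""
        rec = self.records
        rec = rec[np.isfinite(rec["score"])]
        if self.model.catalog is not None:
            rec = rec[rec["programmed"]]
        if require_high_confidence:
            rec = rec[rec["high_confidence"]]
        agg = "max" if self.model.position_agg == "max" else "mean"
        by_pos = rec.groupby("codon_index")["score"].agg(agg)
        idx = pd.RangeIndex(1, self.model.n_codons + 1, name="position")
        return by_pos.reindex(idx)

    def zscore_profile(self, interaction: str,
                       require_high_confidence: bool = False) -> PerturbationProfile:
        scores = self.position_scores(require_high_confidence)
        return PerturbationProfile(interaction, scores, _zscore(scores),
                                   replicates=(interaction,))

    # -- reporting -------------------------------------------------------------

    def summary(self) -> str:
        tab = self.fit_table()
        n_hc = int(self.records["high_confidence"].sum())
        lines = [
            "Codon-specific enrichment model",
            f"  codons fitted: {int(tab['valid'].sum())} of {len(tab)}"
            f"   positions: {self.model.n_codons}",
            f"  scored records: {int(np.isfinite(self.records['score']).sum())}"
            f"   high-confidence: {n_hc}"
            f" (cutoff {self.model.read_cutoff} reads,"
            f" mode {self.model.confidence_mode})",
            "",
            f"  {'codon':>6} {'n_pos':>6} {'slope':>9} {'intercept':>10} "
            f"{'MAE':>9} {'resid_scale':>12}",
        ]
        for _, r in tab[tab["valid"]].iterrows():
            lines.append(f"  {r.codon:>6} {r.n_positions:>6d} {r.slope:>9.3f} "
                         f"{r.intercept:>10.2f} {r.mae:>9.2f} "
                         f"{r.residual_scale:>12.2f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# replicate combination and hotspots
# ---------------------------------------------------------------------------

def combine_replicates(profiles: Sequence[PerturbationProfile],
                       interaction: Optional[str] = None) -> PerturbationProfile:
    """Position-wise mean of replicate Z-scores (missing ignored per position).

    Z-scores are computed per replicate sample *before* combination; the
    combined track keeps replicate provenance.
    """
    if not profiles:
        raise ValueError("no profiles to combine")
    zs = pd.concat([p.z for p in profiles], axis=1)
    scores = pd.concat([p.scores for p in profiles], axis=1)
    combined_z = zs.mean(axis=1, skipna=True)
    combined_scores = scores.mean(axis=1, skipna=True)
    reps = tuple(r for p in profiles for r in (p.replicates or (p.interaction,)))
    return PerturbationProfile(
        interaction or profiles[0].interaction,
        combined_scores, combined_z, replicates=reps,
    )


@dataclass(frozen=True)
class Hotspot:
    """A contiguous run of elevated smoothed Z-scores."""

    start: int                   # 1-based inclusive, profile coordinates
    end: int
    mean_z: float
    iso1_start: Optional[int] = None
    iso1_end: Optional[int] = None


def detect_hotspots(
    profile: PerturbationProfile,
    window: int = 9,
    z_threshold: float = 1.5,
    min_run: int = 5,
    iso_map: Optional[IsoformMap] = None,
) -> list[Hotspot]:
    """Maximal runs of window-smoothed Z >= threshold, length >= min_run."""
    z = profile.z
    smooth = z.rolling(window, center=True, min_periods=1).mean()
    above = (smooth >= z_threshold) & smooth.notna()
    hotspots: list[Hotspot] = []
    run_start = None
    positions = list(z.index)
    for pos, flag in zip(positions, above.to_numpy()):
        if flag and run_start is None:
            run_start = pos
        elif not flag and run_start is not None:
            hotspots.append(_make_hotspot(run_start, pos - 1, smooth, iso_map))
            run_start = None
    if run_start is not None:
        hotspots.append(_make_hotspot(run_start, positions[-1], smooth, iso_map))
    return [h for h in hotspots if h.end - h.start + 1 >= min_run]


def _make_hotspot(start, end, smooth, iso_map) -> Hotspot:
    mean_z = float(smooth.loc[start:end].mean())
    iso1_start = iso1_end = None
    if iso_map is not None:
        s, st1 = iso_map.alt_to_ref(int(start))
        e, st2 = iso_map.alt_to_ref(int(end))
        iso1_start = s if st1 is not MapStatus.UNMAPPED else None
        iso1_end = e if st2 is not MapStatus.UNMAPPED else None
    return Hotspot(int(start), int(end), mean_z, iso1_start, iso1_end)


def hotspots_to_tsv(hotspots: Sequence[Hotspot], path,
                    header_lines: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("# coordinates: isoform-7 residue index, 1-based inclusive; "
                 "iso1_* give reference-isoform coordinates\n")
        pd.DataFrame([h.__dict__ for h in hotspots]).to_csv(fh, sep="\t",
                                                            index=False)


def plot_profile(profile: PerturbationProfile, ax=None, **kwargs):
    """Simple per-position Z-score track plot."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 2.2))
    ax.plot(profile.z.index, profile.z.to_numpy(), lw=0.8, **kwargs)
    ax.set_xlabel("position (isoform-7 residue)")
    ax.set_ylabel("Z")
    ax.set_title(profile.interaction)
    return ax
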