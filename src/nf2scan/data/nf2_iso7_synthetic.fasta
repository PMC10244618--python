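>NF2-iso7_synthetic 507aa synthetic stand-in derived from NF2-iso1_synthetic (del 39-121, exon16 tail)
MLGTALCGSFAPKTETAVCLLDGDSCVPISTAQVFSDSGKEAFCKYWGVQLSRNKRDYLL
TPIQDNTGEYVDAKNHDATESGVVAMTNLSAKKPLSTDPEIGASFAHSINNDRVRDSENI
QLYLTNSQNCLFYPVEHYATDNALSEKLSLLIVDALGLIVYTENKRLPPVLAFPWEEIND
ESSLILLRKIPDLAGAKGSIGPLVQTYGVKCPLWFMCSANHEPLMLVGKVRRWIESTFSK
DRNFELQLKLLWILSLWPEGDWRAYTTRADEAARIQSRNPGNPESIIQVGMFQDTNFQNK
ELKEFVVNGEITKSEIVEYVYRTSDRECLYSHATKVHSGWNLDNYKLVEERESHTGPASL
WFSHTEEPSIVVPTLSSGPWGIEKGLYKPELTKDSFTYPCSNFYDLWIGIALLEIATPQG
SLIEEDHLVAHMITSSSFTEITGGYALHDRTLRKVMSIDNSNYKVHDLIIHDTKPHVGEA
AGNLQHGIKRSLSHDSPQAQGRRPICI
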