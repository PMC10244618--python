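>NF2-iso1_synthetic 595aa synthetic stand-in (anchored residues only are meaningful)
MLGTALCGSFAPKTETAVCLLDGDSCVPISTAQVFSDSVRPFASGCQANTTQFYNVTSST
LVPYDGSYGYTHSASKTLWQIQTSNLREVSGDGANWLAIQVKQPIEEKFKSEGTMIKLYA
EGKEAFCKYWGVQLSRNKRDYLLTPIQDNTGEYVDAKNHDATESGVVAMTNLSAKKPLST
DPEIGASFAHSINNDRVRDSENIQLYLTNSQNCLFYPVEHYATDNALSEKLSLLIVDALG
LIVYTENKRLPPVLAFPWEEINDESSLILLRKIPDLAGAKGSIGPLVQTYGVKCPLWFMC
SANHEPLMLVGKVRRWIESTFSKDRNFELQLKLLWILSLWPEGDWRAYTTRADEAARIQS
RNPGNPESIIQVGMFQDTNFQNKELKEFVVNGEITKSEIVEYVYRTSDRECLYSHATKVH
SGWNLDNYKLVEERESHTGPASLWFSHTEEPSIVVPTLSSGPWGIEKGLYKPELTKDSFT
YPCSNFYDLWIGIALLEIATPQGSLIEEDHLVAHMITSSSFTEITGGYALHDRTLRKVMS
IDNSNYKVHDLIIHDTKPHVGEAAGNLQHGIKRSLSHDSLTLQSAKSRVADTVGD
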