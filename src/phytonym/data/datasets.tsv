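# Dataset registry: datasetID <tab> display name.
# Order defines the tie-break priority used when match candidates are
# otherwise equal.  Extend or override via a config file.
COL	Catalogue of Life
COLChina	Catalogue of Life China
GBIF	GBIF Backbone Taxonomy
LCVP	Leipzig Catalogue of Vascular Plants
POWO	Plants of the World Online
WFO	World Flora Online
SYNTH	Synthetic fixture backbone
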