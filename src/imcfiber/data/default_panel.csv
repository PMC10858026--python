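marker_name,metal_tag,channel_index,target_class
TE7,115In,0,ecm
aSMA,141Pr,1,vessel
Collagen VI,143Nd,2,ecm
Perilipin,145Nd,3,fat
Laminin,149Sm,4,fiber_marker
CD31,151Eu,5,vessel
Collagen III,152Sm,6,ecm
TGFb,154Sm,7,cytokine
CD68,159Tb,8,cell_marker
PDGFRa,162Dy,9,ecm
CTGF,166Er,10,cytokine
PDGFA,167Er,11,cytokine
CD206,168Er,12,cell_marker
Collagen I,169Tm,13,ecm
MYH3,174Yb,14,fiber_marker
CD56,176Yb,15,cell_marker
DNA,191Ir,16,nuclei
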