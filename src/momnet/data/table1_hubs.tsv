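identifier	frequency	dataset_serials	ptm_detected	large_change
PKC	6	1,2,3,4,5,6	Y	Y
UBC	6	1,2,3,4,5,6
TGF-β	5	1,2,3,5,6
ERK	5	1,2,3,5,6	Y	Y
ERK1/2	5	1,2,3,5,6	Y	Y
Jnk	5	1,2,3,5,6	Y	Y
MAPK	5	1,2,3,5,6	Y	Y
Akt	5	1,2,3,5,6	Y	Y
PI3K complex	5	1,2,3,5,6	Y	Y
NFκB Complex	5	1,2,3,5,6	Y	Y
Immunoglobulin	5	1,2,3,5,6
Lh	5	1,2,3,5,6
Insulin	5	1,2,3,5,6
LDL	5	1,2,3,5,6
Integrin	4	1,2,3,5
VEGF	4	1,2,3,5
PDGF BB	4	1,2,3,5
Ras	4	1,2,3,5
Mek	4	1,2,3,5	Y	Y
p38 MAPK	4	2,3,5,6	Y	Y
PKA	4	2,3,5,6	Y	N
FAK	4	2,3,5,6	Y	Y
Creb	4	1,2,3,5	Y	N
Histone h3	4	2,3,4,5	Y	Y
Estrogen receptor	4	1,2,3,5
GH1	4	1,2,3,6
Growth hormone	4	1,2,3,5
Cytochrome C	4	1,2,3,5
AP1	4	1,2,3,5	Y	Y
ADCY	4	1,2,3,6
Actin	3	1,3,5	Y	N
F-Actin	3	1,3,5
Rock	3	1,2,3	Y	N
Collagens	3	1,3,5
Collagen type I	3	2,3,5
Laminin	3	1,3,5
p85	3	2,3,5	Y	Y
p70S6K	3	1,3,5
Rac	3	1,5,6	Y	Y
Shc	3	2,3,5	Y	Y
Ubiquitin	3	2,3,5
HSP90	3	2,3,5	Y	Y
Cyclin A	3	1,3,5
IgG	3	2,3,6
TCR	3	2,3,5
IgE	3	1,2,3
IFNG	3	3,5,6
IFN-α	3	3,4,5
B-estradiol	3	1,3,5
FSH	3	1,2,5
Proinsulin	3	1,2,3
AMPK	3	1,3,5
STAT5a/b	3	1,2,3	Y	N
Caspase	3	2,3,5	Y	N
Calmodulin	3	3,5,6	Y	Y
Calpain	3	1,3,5
PLC	3	2,3,6	Y	Y
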