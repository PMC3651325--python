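# Synthetic sample gene/protein lexicon (50 common human gene symbols/names).
# One entry per line; optional TAB-separated source tag.
BRCA1	human
BRCA2	human
TP53	human
p53	human
TNF	human
tumor necrosis factor	human
IL-2	human
interleukin 2	human
IL-6	human
EGFR	human
epidermal growth factor receptor	human
VEGF	human
MYC	human
KRAS	human
NRAS	human
BRAF	human
PTEN	human
RB1	human
APC	human
MLH1	human
MSH2	human
ATM	human
CHEK2	human
CDK2	human
CDK4	human
cyclin D1	human
CCND1	human
ERBB2	human
HER2	human
ESR1	human
estrogen receptor	human
AR	human
androgen receptor	human
JAK2	human
STAT3	human
NF-kB	human
MAPK1	human
AKT1	human
PIK3CA	human
mTOR	human
GAPDH	human
actin beta	human
ACTB	human
MyoD	human
NOTCH1	human
WNT1	human
SHH	human
GLI1	human
SMAD4	human
TGF beta 1	human
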