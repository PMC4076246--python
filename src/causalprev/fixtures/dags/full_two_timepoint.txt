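# Full two-time-point causal model of COC use and cervical precancer,
# drawn with nodes duplicated at times 0 and 1 so that every edge points
# forward in time (no reverse causation).  Stylized reconstruction of
# the hypothesized model: the published figure is an image, so this
# fixture captures its stated structure (time-ordered unidirectional
# edges; exclusion restrictions such as HPV not causing behavior or
# immune status; COC reaching CIN2+ only via HPV acquisition or disease
# progression), not its exact edge list.
# Node key: SP = sexual partnership, COC = combined oral contraception,
# HAART = antiretroviral therapy, CD4 = immune status, U = unknown causes.
U -> Education
U -> SP_0
U -> COC_0
U -> Condom_0
U -> Gravidity_0
U -> CD4_0
U -> HAART_0
U -> HPV_0
U -> SP_1
U -> COC_1
U -> Condom_1
U -> Gravidity_1
U -> CD4_1
U -> HAART_1
U -> HPV_1
U -> CIN2_1
Education -> SP_0
Education -> COC_0
Education -> Condom_0
Education -> Gravidity_0
SP_0 -> COC_0
SP_0 -> Condom_0
SP_0 -> HPV_0
COC_0 -> Condom_0
COC_0 -> Gravidity_0
COC_0 -> HPV_0
Condom_0 -> Gravidity_0
Condom_0 -> HPV_0
CD4_0 -> HAART_0
CD4_0 -> HPV_0
SP_0 -> SP_1
COC_0 -> COC_1
Condom_0 -> Condom_1
Gravidity_0 -> Gravidity_1
CD4_0 -> CD4_1
HAART_0 -> CD4_1
HAART_0 -> HAART_1
HPV_0 -> HPV_1
Education -> SP_1
Education -> COC_1
Education -> Condom_1
SP_1 -> COC_1
SP_1 -> Condom_1
SP_1 -> HPV_1
COC_1 -> Condom_1
COC_1 -> Gravidity_1
COC_1 -> HPV_1
COC_1 -> CIN2_1
Condom_1 -> HPV_1
Gravidity_0 -> COC_1
CD4_1 -> HPV_1
CD4_1 -> CIN2_1
HPV_0 -> CIN2_1
HPV_1 -> CIN2_1
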