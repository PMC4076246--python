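# Worked DAG example A: classic confounding.
# W may cause both X and Y; X may cause Y.  Exogenous U nodes are
# ordinary graph nodes with no shared causes (U_X independent of U_W).
# Sufficient adjustment set: {W}.
U_X -> X
U_Y -> Y
U_W -> W
W -> X
W -> Y
X -> Y
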