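# Worked DAG example B: collider structure.
# X and Y both cause W; the path X-W-Y is closed because the arrows
# collide at W, and conditioning on W would open it (collider bias).
# Sufficient adjustment set: {} (adjust for nothing).
U_X -> X
U_Y -> Y
U_W -> W
X -> W
Y -> W
X -> Y
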