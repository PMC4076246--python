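# Worked DAG example C: adjusting for one confounder (W3) opens a new
# biasing path through W1 and W2, which must then be blocked by either.
# Sufficient adjustment sets: {W1, W3} and {W2, W3}.
#
# The source figure is an image; this wiring is the canonical structure
# consistent with every stated fact about the example (open backdoor
# X - W3 - Y; conditioning on W3 opens X - W1 - W2 - Y; minimal sets
# {W1, W3} and {W2, W3}).
W1 -> X
W3 -> X
X -> Y
W3 -> Y
W2 -> Y
W1 -> W3
W2 -> W3
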