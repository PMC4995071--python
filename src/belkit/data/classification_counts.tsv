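# Published label counts of the BEL sentence-classification corpus:
# 1554 statement-excerpt pairs with fully/partially supportive labels.
# Columns: key, count.
n	1554
fully_true	578
partially_true	804
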