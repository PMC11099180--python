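# Five-taxon illustrative replicator network, reactions exactly as listed:
# inflow of a; b self-replicates; c needs a; d assisted by a (as listed);
# e needs b and c; every taxon decays.
-> a
b -> 2 b
c + a -> a + 2 c
a + d -> a + 2 d
e + b + c -> b + c + 2 e
a ->
b ->
c ->
d ->
e ->
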