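# Variant of the five-taxon network with d assisted by b instead of a,
# matching the narrative description of the same system ("d needs b to
# replicate"); shipped because the listed and described rules differ.
-> a
b -> 2 b
c + a -> a + 2 c
b + d -> b + 2 d
e + b + c -> b + c + 2 e
a ->
b ->
c ->
d ->
e ->
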