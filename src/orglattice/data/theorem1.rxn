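# Replicator system whose organization family shows that the
# intersection of two organizations need not be self-maintaining.
A -> 2 A
B -> 2 B
A + C -> 2 C
B + C -> 2 C
C ->
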