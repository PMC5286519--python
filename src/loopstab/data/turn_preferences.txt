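# Positional residue preferences for beta-turn back-to-consensus design.
# Format: TYPE POSITION: comma-separated one-letter residues.
# Type II, all four positions; type I, positions 3 and 4. Type I positions
# 1 and 2 are not covered by these statistics; supply a user table to design
# against them.
II 1: C,P
II 2: A,E,K,P
II 3: G,N
II 4: C,D,K,Q,S,T
I 3: D,N,S,T
I 4: C,G,N
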