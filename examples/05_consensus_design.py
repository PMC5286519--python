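"""Back-to-consensus β-turn mutation design on the packaged turn table.

The packaged table annotates the type I/II β-turns of the transketolase
flexible loops.  Non-conforming residues are mutated toward the residues
statistically preferred at their (turn type, position); residues shared by
overlapping turns take the union of preferences across their roles.
"""

import warnings

from loopstab import candidates_to_table, propose_mutations
from loopstab.structure import LoopDefinition
from loopstab.turns import load_turns, packaged_turn_table

FLEXIBLE_LOOPS = [
    LoopDefinition(6, "A", 138, 148),
    LoopDefinition(13, "A", 245, 257),
    LoopDefinition(15, "A", 278, 287),
    LoopDefinition(17, "A", 331, 337),
]

turns = load_turns(packaged_turn_table())
with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # type I pos 1-2 statistics not shipped
    candidates = propose_mutations(turns, restrict_to_loops=FLEXIBLE_LOOPS)

df = candidates_to_table(candidates)
print(df.to_string(index=False))
print(f"\n{len(df)} candidates in total; "
      f"{(df.loop_id == 13).sum()} in loop 245-257; "
      f"K254 targets: {''.join(sorted(df[df.residue == 254].proposed))}")
# 40 single variants; the triple-shared Lys254 collects the union set
# C,D,G,N,P,S,T of its three turn roles.
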