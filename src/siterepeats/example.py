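"""The canonical four-taxon, five-site worked example.

Tree ``((t1,t2)w,(t3,t4)v)u`` with alignment

    t1  AACCA
    t2  CCGGC
    t3  ACGAC
    t4  CTAGT

At cherry ``w`` sites 1, 2 and 5 share the tip pattern "A C" and sites 3
and 4 share "C G", so only two CLV entries are needed there.  At cherry
``v`` sites 2 and 5 share "C T".  At the root ``u`` sites 2 and 5 are the
only repeats (full column "A C C T").  A repeat-aware traversal therefore
computes 2 + 4 + 4 = 10 CLV entries instead of the plain 3 x 5 = 15.
"""

from __future__ import annotations

from .alignment import Alignment
from .trees import Tree, parse_newick

#: branch lengths are immaterial for repeat detection; these are only used
#: by the likelihood demonstrations.
EXAMPLE_NEWICK = "((t1:0.1,t2:0.1):0.05,(t3:0.12,t4:0.07):0.05);"

EXAMPLE_SEQUENCES = [
    ("t1", "AACCA"),
    ("t2", "CCGGC"),
    ("t3", "ACGAC"),
    ("t4", "CTAGT"),
]


def worked_example() -> tuple[Tree, Alignment]:
    """The rooted example tree and its encoded five-site alignment."""
    tree = parse_newick(EXAMPLE_NEWICK)
    alignment = Alignment.from_sequences(EXAMPLE_SEQUENCES)
    return tree, alignment
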