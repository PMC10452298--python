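"""Small built-in example data: a five-taxon tree and its toy trait table.

The tree reproduces the worked five-species covariance matrix used
throughout the documentation: tips x, y, z, u, v all at depth 560, with
MRCA depths c(y,z) = 459, c(y,u) = c(z,u) = 217, c(., v) = 20 and x
splitting at the root.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tree import PhyloTree, parse_newick

__all__ = [
    "FIVE_TAXON_NEWICK",
    "five_taxon_tree",
    "five_taxon_covariance_expected",
    "toy_table",
]

FIVE_TAXON_NEWICK = "(x:560,(v:540,(u:343,(y:101,z:101):242):197):20);"

# labels in newick tip order
_FIVE_TAXON_LABELS = ["x", "v", "u", "y", "z"]
_FIVE_TAXON_C = {
    ("x", "x"): 560, ("y", "y"): 560, ("z", "z"): 560, ("u", "u"): 560,
    ("v", "v"): 560, ("y", "z"): 459, ("y", "u"): 217, ("z", "u"): 217,
    ("y", "v"): 20, ("z", "v"): 20, ("u", "v"): 20,
    ("x", "y"): 0, ("x", "z"): 0, ("x", "u"): 0, ("x", "v"): 0,
}


def five_taxon_tree() -> PhyloTree:
    """The five-taxon example tree (height 560 time units)."""
    return parse_newick(FIVE_TAXON_NEWICK)


def five_taxon_covariance_expected(labels=None) -> np.ndarray:
    """The known shared-branch-length matrix of the example tree."""
    labels = list(labels) if labels is not None else _FIVE_TAXON_LABELS
    n = len(labels)
    C = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            C[i, j] = _FIVE_TAXON_C.get((a, b), _FIVE_TAXON_C.get((b, a)))
    return C


def toy_table() -> pd.DataFrame:
    """Toy five-species trait table: counts y and one quantitative covariate x.

    Tip order (x, y, z, u, v) with y = (2, 8, 12, 5, 16) and
    x = (23.4, 26.7, 24.5, 30.6, 32.5).
    """
    return pd.DataFrame(
        {
            "y": [2, 8, 12, 5, 16],
            "x": [23.4, 26.7, 24.5, 30.6, 32.5],
        },
        index=pd.Index(["x", "y", "z", "u", "v"], name="species"),
    )
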