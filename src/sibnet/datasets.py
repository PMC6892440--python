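"""Small packaged datasets used as worked examples.

``load_signaling_membership`` returns a published worked example of the
pipeline's final report: 20 recurrent synaptome genes found with severe-only
qualifying variants in a 126-patient large-Δ cohort, with their per-gene
patient counts and their membership in six neural signaling networks
(PI3K-AKT-mTOR, NGF-PC12, AVB3-INTEGRIN, PI3K-ERBB2/4, SEMA3A-PKA, REELIN).
"""

from __future__ import annotations

from importlib import resources
from typing import Dict, List, Set, Tuple

import pandas as pd

__all__ = ["load_signaling_membership"]

SIGNALING_COHORT_SIZE = 126


def load_signaling_membership() -> Tuple[List[str], Dict[str, Set[str]], Dict[str, int]]:
    """Load the packaged gene/network membership example.

    Returns ``(genes, networks, patient_counts)`` in the shape expected by
    :func:`sibnet.membership.build_membership_matrix`: the ordered gene list,
    a mapping from network name to its member genes, and the per-gene
    patient counts.
    """
    with resources.files("sibnet.data").joinpath("signaling_network_membership.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t", index_col="gene")
    genes = list(table.index)
    patient_counts = table["patients"].astype(int).to_dict()
    networks = {
        col: set(table.index[table[col] == 1]) for col in table.columns if col != "patients"
    }
    return genes, networks, patient_counts
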