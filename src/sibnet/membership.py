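"""Gene × signaling-network membership matrix with per-gene patient counts.

This is the final report object of the pipeline: for each recurrent gene, the
number of large-Δ-cohort patients carrying a severe-only qualifying variant in
that gene, and boolean membership in each named signaling network.  The
per-network tallies are defined as column sums — the gene count is the number
of member genes, the patient sum is the sum of the member genes' patient
counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["MembershipMatrix", "build_membership_matrix"]


@dataclass
class MembershipMatrix:
    """Boolean gene × network membership plus per-gene patient counts."""

    membership: pd.DataFrame  # bool, index = genes, columns = network names
    patient_counts: pd.Series  # int, index = genes
    total_patients: Optional[int] = None

    def gene_counts(self) -> pd.Series:
        """Member genes per network (column sums of the boolean matrix)."""
        return self.membership.sum(axis=0).astype(int)

    def patient_sums(self) -> pd.Series:
        """Sum of member genes' patient counts per network."""
        return self.membership.T.astype(int).dot(self.patient_counts).astype(int)

    @property
    def genes(self):
        return list(self.membership.index)

    @property
    def networks(self):
        return list(self.membership.columns)

    def to_frame(self) -> pd.DataFrame:
        """Report layout: one gene per row, tally rows appended at the bottom."""
        body = self.membership.map(lambda x: "+" if x else "")
        body.insert(0, "patients", self.patient_counts)
        tallies = pd.DataFrame(
            {
                "patients": ["", "" if self.total_patients is None else self.total_patients],
                **{
                    net: [self.gene_counts()[net], self.patient_sums()[net]]
                    for net in self.networks
                },
            },
            index=["n_genes", "n_patients"],
        )
        return pd.concat([body, tallies])


def build_membership_matrix(
    genes: Sequence[str],
    networks: Mapping[str, Iterable[str]],
    patient_counts: Mapping[str, int],
    total_patients: Optional[int] = None,
) -> MembershipMatrix:
    """Assemble the membership matrix for ``genes`` across named networks.

    ``patient_counts`` must cover every gene; genes appearing in a network
    definition but not in ``genes`` are logged and ignored.  Patient counts
    must not exceed ``total_patients`` when given.
    """
    genes = list(dict.fromkeys(genes))
    missing = [g for g in genes if g not in patient_counts]
    if missing:
        raise ValueError(f"patient_counts missing for genes: {missing[:5]} ...")
    counts = pd.Series({g: int(patient_counts[g]) for g in genes}, name="patients")
    if (counts < 0).any():
        raise ValueError("patient counts must be non-negative")
    if total_patients is not None and (counts > total_patients).any():
        raise ValueError("per-gene patient count exceeds the cohort size")
    gene_set = set(genes)
    data = {}
    for name, members in networks.items():
        members = set(members)
        unknown = members - gene_set
        if unknown:
            logger.warning(
                "network %s: ignoring %d genes not in the gene list (%s...)",
                name, len(unknown), sorted(unknown)[:3],
            )
        data[name] = [g in members for g in genes]
    membership = pd.DataFrame(data, index=genes, columns=list(networks))
    return MembershipMatrix(
        membership=membership, patient_counts=counts, total_patients=total_patients
    )
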