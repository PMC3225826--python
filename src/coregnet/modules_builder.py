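"""Construction of CRM-miRNA combinatorial modules.

A module is the intersection of one CRM's target-gene set with one miRNA's
target-gene set; intersections with fewer than two genes are dropped.
"""

from __future__ import annotations

from .containers import CRMiRNAModule, TargetMap


def build_modules(
    crm_targets: TargetMap, mirna_targets: TargetMap, min_size: int = 2
) -> list[CRMiRNAModule]:
    """One module per (CRM, miRNA) pair whose target intersection has
    >= ``min_size`` genes, ordered lexicographically by (crm_id, mirna_id).
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2 (a pair needs two genes)")
    modules: list[CRMiRNAModule] = []
    for crm_id in sorted(crm_targets.entries):
        crm_genes = crm_targets.entries[crm_id]
        for mirna_id in sorted(mirna_targets.entries):
            shared = crm_genes & mirna_targets.entries[mirna_id]
            if len(shared) >= min_size:
                modules.append(CRMiRNAModule(crm_id, mirna_id, frozenset(shared)))
    return modules
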