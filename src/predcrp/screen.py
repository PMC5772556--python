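"""Consensus screening of candidate (weak-evidence) binding sites.

CRP binds a well-known 22-bp palindromic consensus; the G at positions 5
and 7 and the C at positions 16 and 18 (1-based within the core) provide
most of the binding free energy, and only those four positions are
enforced here.  Sites passing the screen are annotated with the roles
predicted by both the SVM model and the interpretable ruleset;
disagreements are flagged, never suppressed.
"""

from __future__ import annotations

import pandas as pd

from .features import DescriptorSpec, feature_matrix
from .rules import RuleSet, apply_ruleset
from .selection import PredictorModel
from .sites import SiteDataset

CONSENSUS_POSITIONS = {5: "G", 7: "G", 16: "C", 18: "C"}
CORE_LENGTH = 22


def consensus_check(core_seq: str) -> bool:
    """True iff the 22-nt core has G at positions 5 and 7 and C at 16 and
    18 (1-based)."""
    if len(core_seq) != CORE_LENGTH:
        raise ValueError(
            f"consensus_check needs a {CORE_LENGTH}-nt core, got {len(core_seq)} nt"
        )
    seq = core_seq.upper()
    return all(seq[pos - 1] == base for pos, base in CONSENSUS_POSITIONS.items())


def screen_candidates(
    weak_sites: SiteDataset,
    model: PredictorModel | None,
    ruleset: RuleSet,
    spec: DescriptorSpec | None = None,
) -> pd.DataFrame:
    """Screen candidate sites by the consensus criterion and predict roles.

    Sites must already be extended (42 nt); input roles are never altered —
    the report is an append-only annotation.
    """
    spec = spec or DescriptorSpec()
    rows = []
    passing = [s for s in weak_sites if consensus_check(s.core_seq)]
    features = (
        feature_matrix(SiteDataset(list(passing), name="passing"), spec)
        if passing
        else None
    )
    if model is not None and features is not None:
        model_labels, _ = model.predict(features)
        model_roles = dict(zip(features.index, model_labels))
    else:
        model_roles = {}

    for site in weak_sites:
        passes = consensus_check(site.core_seq)
        rule_role, matched = ("", [])
        model_role = ""
        if passes:
            rule_role, matched = apply_ruleset(features.loc[site.site_id], ruleset)
            model_role = model_roles.get(site.site_id, "")
        rows.append(
            {
                "site_id": site.site_id,
                "gene": site.gene,
                "passes_consensus": passes,
                "model_role": model_role,
                "ruleset_role": rule_role,
                "matched_rules": ",".join(matched),
                "disagreement": bool(
                    passes and model_role and rule_role and model_role != rule_role
                ),
                "annotated_role": site.role,
            }
        )
    return pd.DataFrame(rows)
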