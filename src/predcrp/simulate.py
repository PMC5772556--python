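"""Synthetic CRP-like binding-site datasets.

The generator emulates the curated CRP dataset: 22-bp sites carrying the
consensus G/G/C/C at core positions 5/7/16/18, placed on the TSS-relative
axis so that each site's ``Region`` (center) satisfies exactly one of the
four canonical rules — or an "uncovered" tail — and labeled with that
rule's consequent, optionally corrupted by label noise.  Because 22-bp
sites have half-integer centers, rule thresholds like -49.5 are exactly
representable, and a configurable fraction of sites is placed exactly on
them to stress endpoint conventions.

Sites assigned to a later rule in the first-match order [A1, A2, R1, R2]
get blocking motifs planted (e.g. AACG to knock out A2 for an R1 site
whose region also lies in A2's band) so that first-match classification
reproduces the assigned rule exactly.  Uncovered-tail sites sit at
Region < -80 with three TTTT motifs planted, which defeats A1; their
labels are drawn to bring the overall repressor fraction to its target.
Flanks are generated and recorded, so flank extension is exact in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .rules import RuleSet, apply_ruleset, canonical_ruleset
from .screen import CONSENSUS_POSITIONS
from .sites import (
    ROLE_ACTIVATOR,
    ROLE_REPRESSOR,
    BindingSite,
    DictFlankSource,
    SiteDataset,
    parse_site_table,
    write_site_table,
)

ALPHABET = "ACGT"
RULE_MOTIFS = ("TTTT", "AACG", "TTAC", "GAGC")

#: mixture over ground-truth rules, proportional to the canonical rule
#: cover counts on the 169-site curated dataset (88/31/14/7) with the
#: remainder in the uncovered tail.
DEFAULT_RULE_WEIGHTS = {
    "A1": 88 / 169,
    "A2": 31 / 169,
    "R1": 14 / 169,
    "R2": 7 / 169,
    "uncovered": 29 / 169,
}

#: inclusive ranges of the site's leftmost position per assigned rule,
#: chosen so center = left + 10.5 satisfies that rule and no earlier one.
_LEFT_RANGES = {
    "A1": [(-100, -60), (39, 60)],  # center <= -49.5 | center >= 49.5
    "A2": [(-59, -39)],  # center in (-49.5, -28.5]
    "R1": [(-59, -21), (-8, 38)],  # center in (-49.5, -10) | (2, 49.5)
    "R2": [(-20, -9)],  # center in [-9.5, 1.5] (R2 minus R1's bands)
    "uncovered": [(-115, -91)],  # center < -80
}

#: branch probabilities where a rule has two region branches (first branch),
#: matching the published per-branch cover counts (87:1 for A1, 9:5 for R1)
_BRANCH_P = {"A1": 87 / 88, "R1": 9 / 14}

#: exactly-representable boundary centers used for boundary enrichment
_BOUNDARY_LEFTS = {
    "A1": [-60, 39],  # centers -49.5, 49.5
    "A2": [-39],  # center -28.5
    "R1": [-21, -8],  # centers -10.5, 2.5
    "R2": [-20, -9],  # centers -9.5, 1.5
    "uncovered": [-91],
}

_CONSEQUENT = {
    "A1": ROLE_ACTIVATOR,
    "A2": ROLE_ACTIVATOR,
    "R1": ROLE_REPRESSOR,
    "R2": ROLE_REPRESSOR,
}


@dataclass
class SynthConfig:
    n_sites: int = 169
    repressor_fraction: float = 36 / 169
    label_noise: float = 0.0
    rule_weights: dict = field(default_factory=lambda: dict(DEFAULT_RULE_WEIGHTS))
    boundary_fraction: float = 0.05
    flank_length: int = 10
    seed: int = 0
    max_attempts: int = 500

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        for p in (self.repressor_fraction, self.label_noise, self.boundary_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        total = sum(self.rule_weights.values())
        if total <= 0:
            raise ValueError("rule_weights must have positive mass")
        self.rule_weights = {k: v / total for k, v in self.rule_weights.items()}


def _motif_counts(seq: str) -> dict[str, float]:
    return {
        f"4mer_{m}": sum(
            1 for i in range(len(seq) - 3) if seq[i : i + 4] == m
        )
        for m in RULE_MOTIFS
    }


def _random_core(rng: np.random.Generator) -> str:
    core = [ALPHABET[i] for i in rng.integers(4, size=22)]
    for pos, base in CONSENSUS_POSITIONS.items():
        core[pos - 1] = base
    return "".join(core)


def _sample_left(rule: str, cfg: SynthConfig, rng: np.random.Generator) -> int:
    if rng.random() < cfg.boundary_fraction:
        lefts = _BOUNDARY_LEFTS[rule]
        return int(lefts[rng.integers(len(lefts))])
    ranges = _LEFT_RANGES[rule]
    if len(ranges) > 1:
        first = rng.random() < _BRANCH_P.get(rule, 0.5)
        lo, hi = ranges[0] if first else ranges[1]
    else:
        lo, hi = ranges[0]
    return int(rng.integers(lo, hi + 1))


def _synthesize_site(
    rule: str,
    cfg: SynthConfig,
    rng: np.random.Generator,
    ruleset: RuleSet,
) -> tuple[str, str, str, int]:
    """Return (core, flank_left, flank_right, left) whose first-match
    classification equals the assigned rule (or is uncovered)."""
    k = cfg.flank_length
    left = _sample_left(rule, cfg, rng)
    center = left + 10.5
    for _ in range(cfg.max_attempts):
        core = _random_core(rng)
        fl = "".join(ALPHABET[i] for i in rng.integers(4, size=k))
        fr = "".join(ALPHABET[i] for i in rng.integers(4, size=k))
        if rule == "uncovered" and k >= 6:
            fl = "TTTTTT" + fl[6:]
        if rule == "R1" and center <= -28.5 and k >= 4:
            # region also lies in A2's band; plant AACG to defeat A2
            fr = fr[:-4] + "AACG"
        extended = fl + core + fr
        values = _motif_counts(extended)
        values["Region"] = center
        role, matched = apply_ruleset(values, ruleset)
        if rule == "uncovered":
            if not matched:
                return core, fl, fr, left
        elif matched and matched[0] == rule:
            return core, fl, fr, left
    raise RuntimeError(
        f"could not synthesize a site for rule {rule} at Region={center} "
        f"within {cfg.max_attempts} attempts; constraints may be unsatisfiable"
    )


def generate_dataset(cfg: SynthConfig) -> tuple[SiteDataset, pd.DataFrame]:
    """Generate a labeled synthetic dataset plus its ground-truth sidecar.

    The sidecar records the assigned rule, the pre-noise role, the planted
    flanks and whether the label was flipped.  All sites are returned
    already extended (core + recorded flanks).
    """
    rng = np.random.default_rng(cfg.seed)
    ruleset = canonical_ruleset()
    rule_names = sorted(cfg.rule_weights)
    probs = np.array([cfg.rule_weights[r] for r in rule_names])
    assigned = [rule_names[i] for i in rng.choice(len(rule_names), size=cfg.n_sites, p=probs)]

    # labels for the uncovered tail: fill toward the target repressor count
    covered_rep = sum(1 for r in assigned if _CONSEQUENT.get(r) == ROLE_REPRESSOR)
    n_unc = sum(1 for r in assigned if r == "uncovered")
    target_rep = cfg.repressor_fraction * cfg.n_sites
    p_rep_unc = min(1.0, max(0.0, (target_rep - covered_rep) / n_unc)) if n_unc else 0.0

    sites: list[BindingSite] = []
    truth_rows = []
    for i, rule in enumerate(assigned):
        core, fl, fr, left = _synthesize_site(rule, cfg, rng, ruleset)
        if rule == "uncovered":
            true_role = ROLE_REPRESSOR if rng.random() < p_rep_unc else ROLE_ACTIVATOR
        else:
            true_role = _CONSEQUENT[rule]
        flipped = rng.random() < cfg.label_noise
        role = true_role
        if flipped:
            role = ROLE_REPRESSOR if true_role == ROLE_ACTIVATOR else ROLE_ACTIVATOR
        site_id = f"syn{i:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        sites.append(
            BindingSite(
                site_id=site_id,
                tf_name="CRP",
                gene=f"g{i:04d}",
                core_seq=core,
                left=left,
                right=left + 21,
                strand=strand,
                evidence="strong",
                role=role,
                tss=1000 + 500 * i,
                extended_seq=fl + core + fr,
            )
        )
        truth_rows.append(
            {
                "site_id": site_id,
                "assigned_rule": rule,
                "true_role": true_role,
                "role": role,
                "label_flipped": flipped,
                "flank_left": fl,
                "flank_right": fr,
            }
        )
    truth = pd.DataFrame(truth_rows).set_index("site_id")
    return SiteDataset(sites, name="synthetic", provenance=f"generated seed={cfg.seed}"), truth


def flank_source_from_truth(truth: pd.DataFrame) -> DictFlankSource:
    return DictFlankSource(
        {
            sid: (row["flank_left"], row["flank_right"])
            for sid, row in truth.iterrows()
        }
    )


def ruleset_label_accuracy(
    features: pd.DataFrame,
    truth: pd.DataFrame,
    ruleset: RuleSet | None = None,
    covered_only: bool = True,
) -> float:
    """Fraction of (rule-covered) sites whose first-match classification
    reproduces the recorded label; the generator/ruleset closed loop."""
    ruleset = ruleset or canonical_ruleset()
    sel = truth if not covered_only else truth[truth["assigned_rule"] != "uncovered"]
    if sel.empty:
        raise ValueError("no covered sites to score")
    correct = 0
    for sid, row in sel.iterrows():
        role, _ = apply_ruleset(features.loc[sid], ruleset)
        correct += int(role == row["role"])
    return correct / len(sel)


def planted_feature_table(
    seed: int,
    n_samples: int = 120,
    n_features: int = 50,
    planted: tuple[int, int] = (3, 17),
    margin: float = 0.4,
) -> tuple[np.ndarray, np.ndarray]:
    """A noise feature table with two planted informative columns.

    Labels are the sign of the planted pair's sum, kept a margin away from
    the boundary, so each planted feature alone carries partial signal
    (~0.85 single-feature CV accuracy) and the pair is perfectly separable;
    all other columns are independent standard normals.  Used for the
    feature-selection recovery experiment.
    """
    rng = np.random.default_rng(seed)
    i, j = planted
    f1 = np.empty(0)
    f2 = np.empty(0)
    while len(f1) < n_samples:
        a = rng.normal(size=4 * n_samples)
        b = rng.normal(size=4 * n_samples)
        keep = np.abs(a + b) >= margin
        f1 = np.concatenate([f1, a[keep]])
        f2 = np.concatenate([f2, b[keep]])
    f1, f2 = f1[:n_samples], f2[:n_samples]
    X = rng.normal(size=(n_samples, n_features))
    X[:, i] = f1
    X[:, j] = f2
    y = np.where(f1 + f2 > 0, ROLE_ACTIVATOR, ROLE_REPRESSOR)
    return X, y


def write_fixture(dataset: SiteDataset, truth: pd.DataFrame, out_dir) -> dict[str, Path]:
    """Write the RegulonDB-dialect TSV, a core-sequence FASTA and the
    ground-truth sidecar; the TSV round-trips through parse_site_table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "sites": out / "sites.tsv",
        "fasta": out / "sites.fasta",
        "truth": out / "truth.tsv",
    }
    write_site_table(dataset, paths["sites"])
    records = [
        SeqRecord(Seq(s.core_seq), id=s.site_id, description=f"gene={s.gene}")
        for s in dataset
    ]
    SeqIO.write(records, paths["fasta"], "fasta")
    truth.to_csv(paths["truth"], sep="\t")
    return paths


def read_fixture(fixture_dir) -> tuple[SiteDataset, pd.DataFrame]:
    d = Path(fixture_dir)
    dataset = parse_site_table(d / "sites.tsv", name="synthetic")
    truth = pd.read_csv(d / "truth.tsv", sep="\t", index_col="site_id")
    return dataset, truth
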