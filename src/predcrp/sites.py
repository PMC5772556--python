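"""Binding-site tables: parsing, curation, flank extension and train/test splits.

Sites live on a continuous TSS-relative axis with the transcription start
site at 0.  A site occupies the closed integer interval ``[left, right]``
(one nucleotide per integer), so a 22-bp site has ``right - left + 1 == 22``
and its center ``(left + right) / 2`` is a half-integer.  Minus-strand sites
are reflected at parse time so that "downstream of the TSS" is always the
positive direction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ROLE_ACTIVATOR = "activator"
ROLE_REPRESSOR = "repressor"
ROLE_UNKNOWN = "unknown"

#: Default column map for the RegulonDB-export-like tab-separated dialect.
DEFAULT_DIALECT: dict = {
    "site_id": "site_id",
    "tf_name": "tf_name",
    "gene": "gene",
    "left": "left",
    "right": "right",
    "tss": "tss",
    "strand": "strand",
    "sequence": "sequence",
    "evidence": "evidence",
    "role": "role",
    # vocabulary for the role column -> canonical labels
    "role_map": {
        "+": ROLE_ACTIVATOR,
        "-": ROLE_REPRESSOR,
        "activator": ROLE_ACTIVATOR,
        "repressor": ROLE_REPRESSOR,
        "unknown": ROLE_UNKNOWN,
        "?": ROLE_UNKNOWN,
    },
}

_MANDATORY = ("tf_name", "left", "right", "tss", "strand", "sequence", "evidence", "role")


class DialectError(ValueError):
    """A mandatory column cannot be resolved through the dialect map."""


@dataclass
class BindingSite:
    """One TSS-anchored transcription-factor binding site."""

    site_id: str
    tf_name: str
    gene: str
    core_seq: str
    left: int
    right: int
    strand: str
    evidence: str
    role: str
    tss: int | None = None
    extended_seq: str | None = None

    @property
    def length(self) -> int:
        return self.right - self.left + 1

    @property
    def center(self) -> float:
        """The rules' ``Region`` variable under default (center) semantics."""
        return (self.left + self.right) / 2.0

    def region(self, semantics: str = "center") -> float:
        if semantics == "center":
            return self.center
        if semantics == "leftmost":
            return float(self.left)
        if semantics == "rightmost":
            return float(self.right)
        raise ValueError(f"unknown region semantics: {semantics!r}")

    def validate(self) -> None:
        if self.length != len(self.core_seq):
            raise ValueError(
                f"site {self.site_id}: interval length {self.length} != "
                f"sequence length {len(self.core_seq)}"
            )
        if self.extended_seq is not None:
            k = (len(self.extended_seq) - len(self.core_seq)) // 2
            if self.extended_seq[k : k + len(self.core_seq)] != self.core_seq:
                raise ValueError(
                    f"site {self.site_id}: extended_seq does not contain "
                    "core_seq as its central segment"
                )


@dataclass
class SiteDataset:
    """An ordered collection of binding sites with provenance."""

    sites: list[BindingSite]
    name: str = "dataset"
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    def __post_init__(self) -> None:
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise ValueError(f"dataset {self.name}: duplicate site_ids")

    def roles(self) -> list[str]:
        return [s.role for s in self.sites]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_id": [s.site_id for s in self.sites],
                "tf_name": [s.tf_name for s in self.sites],
                "gene": [s.gene for s in self.sites],
                "left": [s.left for s in self.sites],
                "right": [s.right for s in self.sites],
                "strand": [s.strand for s in self.sites],
                "evidence": [s.evidence for s in self.sites],
                "role": [s.role for s in self.sites],
                "sequence": [s.core_seq for s in self.sites],
                "extended": [s.extended_seq or "" for s in self.sites],
            }
        )


@dataclass
class RejectReport:
    """Rows that failed to parse, with the reason for each."""

    rows: list[tuple[int, str]] = field(default_factory=list)

    def add(self, row_index: int, reason: str) -> None:
        self.rows.append((row_index, reason))

    def __len__(self) -> int:
        return len(self.rows)


def _relative_interval(left: int, right: int, tss: int, strand: str) -> tuple[int, int]:
    """Map absolute genome coordinates to the TSS-relative axis, strand-aware.

    On the minus strand the axis is reflected so downstream of the TSS is
    positive; reflecting twice restores the original interval.
    """
    if strand == "+":
        return left - tss, right - tss
    if strand == "-":
        return tss - right, tss - left
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")


def parse_site_table(
    path,
    dialect: Mapping | None = None,
    reject_report: RejectReport | None = None,
    name: str = "sites",
) -> SiteDataset:
    """Parse a RegulonDB-export-like TSV of binding sites.

    Coordinates in the file are absolute; the returned sites carry
    TSS-relative closed intervals.  Malformed rows are collected in
    ``reject_report`` (if given) rather than silently dropped.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _MANDATORY if dialect[c] not in table.columns]
    if missing:
        raise DialectError(
            f"mandatory columns not resolvable via dialect map: {missing} "
            f"(file has {list(table.columns)})"
        )
    role_map = dialect["role_map"]
    has_id = dialect["site_id"] in table.columns
    has_gene = dialect.get("gene") in table.columns

    sites: list[BindingSite] = []
    for i, row in table.iterrows():
        try:
            left = int(row[dialect["left"]])
            right = int(row[dialect["right"]])
            tss = int(row[dialect["tss"]])
        except ValueError as exc:
            if reject_report is not None:
                reject_report.add(int(i), f"unparseable coordinate: {exc}")
            continue
        strand = row[dialect["strand"]].strip()
        if strand not in ("+", "-"):
            if reject_report is not None:
                reject_report.add(int(i), f"bad strand {strand!r}")
            continue
        seq = row[dialect["sequence"]].strip().upper()
        rel_left, rel_right = _relative_interval(left, right, tss, strand)
        if rel_right - rel_left + 1 != len(seq):
            if reject_report is not None:
                reject_report.add(
                    int(i),
                    f"interval length {rel_right - rel_left + 1} != sequence length {len(seq)}",
                )
            continue
        raw_role = row[dialect["role"]].strip()
        role = role_map.get(raw_role, role_map.get(raw_role.lower(), ROLE_UNKNOWN))
        sites.append(
            BindingSite(
                site_id=str(row[dialect["site_id"]]) if has_id else f"site{i:04d}",
                tf_name=row[dialect["tf_name"]].strip(),
                gene=str(row[dialect["gene"]]).strip() if has_gene else "",
                core_seq=seq,
                left=rel_left,
                right=rel_right,
                strand=strand,
                evidence=row[dialect["evidence"]].strip().lower(),
                role=role,
                tss=tss,
            )
        )
    return SiteDataset(sites=sites, name=name, provenance=f"parsed from {path}")


@dataclass
class CurationLog:
    """Counts removed at each curation step, in application order."""

    input_count: int = 0
    removed_tf: int = 0
    removed_evidence: int = 0
    removed_redundant: int = 0
    removed_length: int = 0
    output_count: int = 0

    def as_text(self) -> str:
        return (
            f"input sites: {self.input_count}\n"
            f"removed (TF-name filter): {self.removed_tf}\n"
            f"removed (evidence filter): {self.removed_evidence}\n"
            f"removed (TSS-redundancy): {self.removed_redundant}\n"
            f"removed (length filter): {self.removed_length}\n"
            f"retained: {self.output_count}\n"
        )


def curate(
    dataset: SiteDataset,
    tf: str = "CRP",
    evidence: str = "strong",
    core_length: int = 22,
    log: CurationLog | None = None,
) -> SiteDataset:
    """Curate a parsed dataset: TF filter, evidence filter, TSS-redundancy
    removal, and the fixed-core-length filter, applied in that order.

    Redundancy removal drops exact duplicates — sites sharing a TSS with
    identical leftmost and rightmost positions — keeping the first by input
    order.  Curation is idempotent.
    """
    log = log if log is not None else CurationLog()
    log.input_count = len(dataset)

    step1 = [s for s in dataset if s.tf_name.upper() == tf.upper()]
    log.removed_tf = log.input_count - len(step1)

    step2 = [s for s in step1 if s.evidence == evidence]
    log.removed_evidence = len(step1) - len(step2)

    seen: set[tuple] = set()
    step3 = []
    for s in step2:
        key = (s.tss, s.left, s.right)
        if key in seen:
            continue
        seen.add(key)
        step3.append(s)
    log.removed_redundant = len(step2) - len(step3)

    step4 = [s for s in step3 if s.length == core_length]
    log.removed_length = len(step3) - len(step4)
    log.output_count = len(step4)

    return SiteDataset(
        sites=step4,
        name=f"{dataset.name}:curated",
        provenance=dataset.provenance + f" | curated tf={tf} evidence={evidence}",
    )


# ---------------------------------------------------------------------------
# Flank extension


class DictFlankSource:
    """Flanks recorded per site (e.g. by the synthetic generator)."""

    def __init__(self, flanks: Mapping[str, tuple[str, str]]):
        self._flanks = dict(flanks)

    def flanks(self, site: BindingSite, k: int) -> tuple[str, str]:
        up, down = self._flanks.get(site.site_id, ("", ""))
        return up[-k:] if k else "", down[:k] if k else ""


class SequenceFlankSource:
    """Flanks sliced from reference sequences keyed by site gene or id.

    The reference is the promoter-region sequence on the TSS-relative axis;
    ``offset`` gives the axis coordinate of the first base of the reference.
    """

    def __init__(self, references: Mapping[str, str], offset: int):
        self._refs = {k: v.upper() for k, v in references.items()}
        self._offset = offset

    def flanks(self, site: BindingSite, k: int) -> tuple[str, str]:
        ref = self._refs.get(site.site_id) or self._refs.get(site.gene, "")
        lo = site.left - self._offset
        hi = site.right - self._offset
        up = ref[max(0, lo - k) : max(0, lo)]
        down = ref[hi + 1 : hi + 1 + k]
        return up, down


def extend_site(site: BindingSite, flank_source, k: int = 10) -> BindingSite:
    """Extend the core sequence by ``k`` flanking nucleotides on each side.

    With the default k=10 a 22-bp core becomes a 42-bp extended sequence.
    Shortfalls on either flank are N-padded (N contributes to no k-mer
    count) and a warning is logged.  Core coordinates are unchanged.
    """
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    if k == 0:
        return replace(site, extended_seq=site.core_seq)
    up, down = flank_source.flanks(site, k)
    if len(up) < k or len(down) < k:
        warnings.warn(
            f"site {site.site_id}: flank shorter than k={k} "
            f"(got {len(up)}/{len(down)}); N-padding",
            stacklevel=2,
        )
    up = ("N" * (k - len(up)) + up)[-k:]
    down = (down + "N" * (k - len(down)))[:k]
    return replace(site, extended_seq=up + site.core_seq + down)


# ---------------------------------------------------------------------------
# Train/test split


def split_dataset(
    dataset: SiteDataset,
    ratio: tuple[int, int] = (2, 1),
    seed: int = 0,
) -> tuple[SiteDataset, SiteDataset]:
    """Stratified random split by role, deterministic under ``seed``.

    Per class, floor(n * train_frac) sites go to train; remainders are then
    assigned (largest fractional part first) until the overall train size
    matches round(total * train_frac).  With 169 sites (133 activators, 36
    repressors) and ratio 2:1 this yields the 113/56 partition with 89/24
    activators/repressors in train and 44/12 in test.
    """
    train_w, test_w = ratio
    if train_w < 0 or test_w < 0 or train_w + test_w == 0:
        raise ValueError(f"bad ratio {ratio}")
    frac = train_w / (train_w + test_w)
    rng = np.random.default_rng(seed)

    by_class: dict[str, list[BindingSite]] = {}
    for s in dataset:
        by_class.setdefault(s.role, []).append(s)
    for role, members in by_class.items():
        if not members:
            warnings.warn(f"class {role!r} has 0 members", stacklevel=2)

    classes = sorted(by_class)
    base = {c: int(np.floor(len(by_class[c]) * frac)) for c in classes}
    target_total = int(round(len(dataset) * frac))
    remainders = sorted(
        classes, key=lambda c: (len(by_class[c]) * frac) % 1.0, reverse=True
    )
    i = 0
    while sum(base.values()) < target_total and i < len(classes):
        c = remainders[i % len(classes)]
        if base[c] < len(by_class[c]):
            base[c] += 1
        i += 1

    train: list[BindingSite] = []
    test: list[BindingSite] = []
    for c in classes:
        members = list(by_class[c])
        order = rng.permutation(len(members))
        n_train = base[c]
        train.extend(members[j] for j in order[:n_train])
        test.extend(members[j] for j in order[n_train:])

    train.sort(key=lambda s: s.site_id)
    test.sort(key=lambda s: s.site_id)
    return (
        SiteDataset(train, name=f"{dataset.name}:train", provenance=dataset.provenance),
        SiteDataset(test, name=f"{dataset.name}:test", provenance=dataset.provenance),
    )


def write_site_table(dataset: SiteDataset, path, tss: int = 0) -> None:
    """Write sites back to the tab-separated dialect (absolute coordinates
    reconstructed from each site's stored TSS; plus-strand convention)."""
    rows = []
    for s in dataset:
        t = s.tss if s.tss is not None else tss
        if s.strand == "+":
            left, right = s.left + t, s.right + t
        else:
            left, right = t - s.right, t - s.left
        rows.append(
            {
                "site_id": s.site_id,
                "tf_name": s.tf_name,
                "gene": s.gene,
                "left": left,
                "right": right,
                "tss": t,
                "strand": s.strand,
                "sequence": s.core_seq,
                "evidence": s.evidence,
                "role": s.role,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
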