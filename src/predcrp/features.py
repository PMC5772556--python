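"""The 380-feature binding-site descriptor.

Layout (fixed order, stable names):

====================  ======  ==========================================
block                 width   contents
====================  ======  ==========================================
4-mer composition      256    overlapping 4-mer counts, lexicographic
3-mer composition       64    overlapping 3-mer counts, lexicographic
location-dependent      17    overlap lengths with promoter windows L1-L17
physicochemical          3    GC fraction, purine fraction, Wallace Tm
global                  40    base fractions (4) + dinucleotide transition
                              frequencies (16) + occurrence-position
                              quantiles per base (20)
====================  ======  ==========================================

Composition, physicochemical and global blocks are computed on the 42-nt
extended sequence; location features on the TSS-relative core interval.
Windows L3 = [-35, -10], L6 = [-10, 2], L12 = [-60, 60] and L15 = [-95, -35]
are fixed; the remaining 13 windows default to a documented tiling of
[-120, 60] around canonical promoter elements and are overridable.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sites import BindingSite

ALPHABET = "ACGT"


@dataclass(frozen=True)
class LocationWindow:
    """A fixed promoter-region window on the TSS-relative axis."""

    name: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"window {self.name}: start must be < end")


#: L3/L6/L12/L15 are the published windows; the rest tile [-120, 60] around
#: canonical promoter landmarks (UP element, -35 box, spacer, -10 box, TSS,
#: downstream region, and the Class I/II activation anchors at -61.5/-41.5).
DEFAULT_WINDOWS: tuple[LocationWindow, ...] = (
    LocationWindow("L1", -120, -95),
    LocationWindow("L2", -95, -60),
    LocationWindow("L3", -35, -10),
    LocationWindow("L4", -60, -35),
    LocationWindow("L5", -40, -30),
    LocationWindow("L6", -10, 2),
    LocationWindow("L7", -15, -5),
    LocationWindow("L8", 2, 20),
    LocationWindow("L9", 20, 40),
    LocationWindow("L10", 40, 60),
    LocationWindow("L11", -120, 0),
    LocationWindow("L12", -60, 60),
    LocationWindow("L13", 0, 60),
    LocationWindow("L14", -80, -40),
    LocationWindow("L15", -95, -35),
    LocationWindow("L16", -52.5, -30.5),
    LocationWindow("L17", -72.5, -50.5),
)


def _kmers(k: int) -> list[str]:
    return ["".join(p) for p in itertools.product(ALPHABET, repeat=k)]


@dataclass
class DescriptorSpec:
    """Named layout of the descriptor; total dimension 380 by default."""

    kmer_sizes: tuple[int, ...] = (4, 3)
    windows: tuple[LocationWindow, ...] = DEFAULT_WINDOWS
    physchem_names: tuple[str, ...] = ("gc_fraction", "purine_fraction", "wallace_tm")
    region_semantics: str = "center"
    #: sequence used for composition blocks: "extended" or "core"
    motif_scope: str = "extended"
    feature_names: list[str] = field(init=False)

    def __post_init__(self) -> None:
        names: list[str] = []
        for k in self.kmer_sizes:
            names.extend(f"{k}mer_{m}" for m in _kmers(k))
        names.extend(f"overlap_{w.name}" for w in self.windows)
        names.extend(self.physchem_names)
        names.extend(f"frac_{b}" for b in ALPHABET)
        names.extend(f"trans_{a}{b}" for a in ALPHABET for b in ALPHABET)
        for b in ALPHABET:
            names.extend(
                f"dist_{b}_{q}" for q in ("first", "q25", "q50", "q75", "last")
            )
        if len(set(names)) != len(names):
            raise ValueError("feature names are not unique")
        self.feature_names = names

    @property
    def dimension(self) -> int:
        return len(self.feature_names)


@dataclass
class FeatureVector:
    """One extracted descriptor, ordered per a DescriptorSpec."""

    site_id: str
    values: np.ndarray
    names: list[str]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def kmer_composition(seq: str, k: int) -> np.ndarray:
    """Overlapping k-mer counts in lexicographic order over {A,C,G,T}.

    Windows containing any non-ACGT symbol (e.g. the N pad) contribute
    nothing.  For an N-free sequence of length L the counts sum to L-k+1.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    seq = seq.upper()
    idx = {m: i for i, m in enumerate(_kmers(k))}
    counts = np.zeros(4**k, dtype=np.int64)
    for i in range(len(seq) - k + 1):
        word = seq[i : i + k]
        j = idx.get(word)
        if j is not None:
            counts[j] += 1
    return counts


def window_overlap(left: float, right: float, window: LocationWindow) -> int:
    """Number of integer nucleotide positions inside both the closed site
    interval [left, right] and the window [start, end]."""
    lo = max(float(left), window.start)
    hi = min(float(right), window.end)
    if lo > hi:
        return 0
    return max(0, int(np.floor(hi)) - int(np.ceil(lo)) + 1)


def physicochemical_descriptor(seq: str) -> np.ndarray:
    """GC fraction, purine fraction and the Wallace-rule melting-temperature
    estimate Tm = 2(A+T) + 4(G+C), all from base composition alone."""
    seq = seq.upper()
    counts = {b: seq.count(b) for b in ALPHABET}
    n = sum(counts.values())
    if n == 0:
        warnings.warn("all-N sequence: physicochemical descriptor is zero", stacklevel=2)
        return np.zeros(3)
    gc = (counts["G"] + counts["C"]) / n
    purine = (counts["A"] + counts["G"]) / n
    tm = 2.0 * (counts["A"] + counts["T"]) + 4.0 * (counts["G"] + counts["C"])
    return np.array([gc, purine, tm])


def global_descriptor(seq: str) -> np.ndarray:
    """40 global sequence features.

    4 base fractions, 16 dinucleotide transition frequencies (normalized by
    the number of ACGT-ACGT steps), and for each base the normalized
    positions (pos/len, 1-based) of its first, 25%, 50%, 75% and last
    occurrence, 0 when the base is absent.
    """
    seq = seq.upper()
    n = len(seq)
    out = np.zeros(40)
    valid = [i for i, c in enumerate(seq) if c in ALPHABET]
    nv = len(valid)
    for bi, b in enumerate(ALPHABET):
        out[bi] = seq.count(b) / nv if nv else 0.0

    steps = [
        (seq[i], seq[i + 1])
        for i in range(n - 1)
        if seq[i] in ALPHABET and seq[i + 1] in ALPHABET
    ]
    if steps:
        for si, (a, b) in enumerate(itertools.product(ALPHABET, ALPHABET)):
            out[4 + si] = sum(1 for s in steps if s == (a, b)) / len(steps)

    for bi, b in enumerate(ALPHABET):
        pos = [i + 1 for i, c in enumerate(seq) if c == b]
        if not pos:
            continue
        marks = [
            pos[0],
            pos[int(np.ceil(0.25 * len(pos))) - 1],
            pos[int(np.ceil(0.50 * len(pos))) - 1],
            pos[int(np.ceil(0.75 * len(pos))) - 1],
            pos[-1],
        ]
        out[20 + 5 * bi : 20 + 5 * bi + 5] = [m / n for m in marks]
    return out


def extract_features(site: BindingSite, spec: DescriptorSpec | None = None) -> FeatureVector:
    """Concatenate [4-mer | 3-mer | location | physicochemical | global]
    into the 380-dimensional descriptor for one extended site."""
    spec = spec or DescriptorSpec()
    if site.extended_seq is None:
        raise ValueError(
            f"site {site.site_id} has no extended_seq; call extend_site first"
        )
    seq = site.extended_seq if spec.motif_scope == "extended" else site.core_seq
    blocks = [kmer_composition(seq, k).astype(float) for k in spec.kmer_sizes]
    blocks.append(
        np.array([window_overlap(site.left, site.right, w) for w in spec.windows], dtype=float)
    )
    blocks.append(physicochemical_descriptor(seq))
    blocks.append(global_descriptor(seq))
    values = np.concatenate(blocks)
    if len(values) != spec.dimension:
        raise AssertionError("descriptor layout out of sync with spec")
    return FeatureVector(site_id=site.site_id, values=values, names=spec.feature_names)


def feature_matrix(dataset, spec: DescriptorSpec | None = None) -> pd.DataFrame:
    """Extract all sites into a DataFrame (rows = sites, columns = features)
    with an extra ``Region`` column for the rules' location variable."""
    spec = spec or DescriptorSpec()
    rows = []
    index = []
    for site in dataset:
        fv = extract_features(site, spec)
        rows.append(fv.values)
        index.append(site.site_id)
    df = pd.DataFrame(np.asarray(rows), index=index, columns=spec.feature_names)
    df.insert(0, "Region", [s.region(spec.region_semantics) for s in dataset])
    return df
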