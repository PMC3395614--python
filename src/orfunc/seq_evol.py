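"""Pairwise evolutionary metrics on codon-aligned odorant-receptor sequences.

Implements the classic desk toolkit for comparing orthologous coding
sequences: Jukes-Cantor nucleotide distance, Grantham amino-acid property
distance (whole ORF or a configured subset of binding-site positions),
pairwise dN/dS by the Nei-Gojobori (1986) counting method with Jukes-Cantor
correction, and Neighbor-Joining tree construction from a distance matrix.

All metrics operate on pre-aligned sequences (codon-aware alignment is an
external step). Gap handling is pairwise deletion at the codon level.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

GAP = "-"

CODON_TABLE = dict(standard_dna_table.forward_table)
STOP_CODONS = set(standard_dna_table.stop_codons)
SENSE_CODONS = sorted(CODON_TABLE)
NUCLEOTIDES = "ACGT"


class AlignmentError(ValueError):
    """Raised when an input violates codon-alignment preconditions."""


class InternalStopError(AlignmentError):
    """Raised when a non-terminal stop codon occurs in an ungapped frame."""

    def __init__(self, codon_index: int, codon: str):
        self.codon_index = codon_index
        self.codon = codon
        super().__init__(f"internal stop codon {codon!r} at codon {codon_index}")


class SaturationError(ValueError):
    """Mismatch proportion >= 3/4: the Jukes-Cantor distance is undefined."""


# ---------------------------------------------------------------------------
# Translation and sequence pairs
# ---------------------------------------------------------------------------

def translate_codon_alignment(nt: str, gap: str = GAP) -> str:
    """Translate an aligned nucleotide string codon-by-codon.

    Gap codons (three gap symbols) map to a single gap residue. A stop codon
    is tolerated only in the terminal codon position, where it is stripped.
    Codons mixing gaps and bases are rejected: gaps must occur in whole-codon
    units for the alignment to stay in frame.
    """
    if len(nt) % 3 != 0:
        raise AlignmentError(f"aligned length {len(nt)} not divisible by 3")
    nt = nt.upper()
    out = []
    n_codons = len(nt) // 3
    for i in range(n_codons):
        codon = nt[3 * i : 3 * i + 3]
        if codon == gap * 3:
            out.append(gap)
            continue
        if gap in codon:
            raise AlignmentError(f"partial-codon gap {codon!r} at codon {i + 1}")
        if codon in STOP_CODONS:
            if i == n_codons - 1:
                break  # terminal stop stripped
            raise InternalStopError(i + 1, codon)
        try:
            out.append(CODON_TABLE[codon])
        except KeyError:
            raise AlignmentError(f"unrecognized codon {codon!r} at codon {i + 1}")
    return "".join(out)


@dataclass(frozen=True)
class CodingSequencePair:
    """A codon-aligned pair of coding sequences and their translations.

    The substrate for every pairwise metric in this module. Construct via
    :meth:`from_nucleotides` to get validation and automatic translation.
    """

    id_a: str
    id_b: str
    nt_a: str
    nt_b: str
    aa_a: str
    aa_b: str

    @classmethod
    def from_nucleotides(cls, id_a: str, nt_a: str, id_b: str, nt_b: str) -> "CodingSequencePair":
        if len(nt_a) != len(nt_b):
            raise AlignmentError(
                f"aligned lengths differ: {len(nt_a)} vs {len(nt_b)}"
            )
        aa_a = translate_codon_alignment(nt_a)
        aa_b = translate_codon_alignment(nt_b)
        # terminal-stop stripping may shorten one translation; pad comparison
        # length by trimming both nucleotide strings to shared codons
        return cls(id_a, id_b, nt_a.upper(), nt_b.upper(), aa_a, aa_b)

    def codon_pairs(self) -> Iterable[tuple[str, str]]:
        """Yield aligned codon pairs where both members are gap-free sense codons."""
        n = min(len(self.nt_a), len(self.nt_b)) // 3
        for i in range(n):
            ca = self.nt_a[3 * i : 3 * i + 3]
            cb = self.nt_b[3 * i : 3 * i + 3]
            if GAP in ca or GAP in cb:
                continue
            if ca in STOP_CODONS or cb in STOP_CODONS:
                continue
            yield ca, cb


# ---------------------------------------------------------------------------
# Jukes-Cantor nucleotide distance
# ---------------------------------------------------------------------------

def jukes_cantor_correction(p: float) -> float:
    """d = -(3/4) ln(1 - (4/3) p); domain p < 3/4."""
    if p >= 0.75:
        raise SaturationError(f"mismatch proportion {p:.4f} >= 3/4; distance undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def jukes_cantor_distance(pair: CodingSequencePair) -> float:
    """Jukes-Cantor nucleotide distance over ungapped aligned sites."""
    sites = 0
    diffs = 0
    for a, b in zip(pair.nt_a, pair.nt_b):
        if a == GAP or b == GAP:
            continue
        sites += 1
        if a != b:
            diffs += 1
    if sites == 0:
        raise AlignmentError("no ungapped comparable sites")
    return jukes_cantor_correction(diffs / sites)


# ---------------------------------------------------------------------------
# Grantham amino-acid property distance
# ---------------------------------------------------------------------------

# Residue physicochemical properties from Grantham (1974):
# composition c (atomic weight ratio of hetero elements), polarity p,
# molecular volume v.
GRANTHAM_PROPERTIES: dict[str, tuple[float, float, float]] = {
    "A": (0.00, 8.1, 31.0),
    "R": (0.65, 10.5, 124.0),
    "N": (1.33, 11.6, 56.0),
    "D": (1.38, 13.0, 54.0),
    "C": (2.75, 5.5, 55.0),
    "Q": (0.89, 10.5, 85.0),
    "E": (0.92, 12.3, 83.0),
    "G": (0.74, 9.0, 3.0),
    "H": (0.58, 10.4, 96.0),
    "I": (0.00, 5.2, 111.0),
    "L": (0.00, 4.9, 111.0),
    "K": (0.33, 11.3, 119.0),
    "M": (0.00, 5.7, 105.0),
    "F": (0.00, 5.2, 132.0),
    "P": (0.39, 8.0, 32.5),
    "S": (1.42, 9.2, 32.0),
    "T": (0.71, 8.6, 61.0),
    "W": (0.13, 5.4, 170.0),
    "Y": (0.20, 6.2, 136.0),
    "V": (0.00, 5.9, 84.0),
}

GRANTHAM_WEIGHTS = {"alpha": 1.833, "beta": 0.1018, "gamma": 0.000399}


@dataclass(frozen=True)
class GranthamTable:
    """20x20 symmetric residue-pair distance matrix.

    Built from composition, polarity and molecular volume with the original
    squared-difference weights; the scale factor is chosen so the mean over
    the 190 unordered heterotypic residue pairs is exactly 100 (the published
    matrix rounds each entry to an integer).
    """

    residues: tuple[str, ...]
    matrix: np.ndarray  # (20, 20)
    _index: dict[str, int] = field(repr=False, default_factory=dict)

    @classmethod
    def from_properties(
        cls,
        properties: dict[str, tuple[float, float, float]] | None = None,
        alpha: float | None = None,
        beta: float | None = None,
        gamma: float | None = None,
        mean_target: float = 100.0,
    ) -> "GranthamTable":
        props = properties or GRANTHAM_PROPERTIES
        a = alpha if alpha is not None else GRANTHAM_WEIGHTS["alpha"]
        b = beta if beta is not None else GRANTHAM_WEIGHTS["beta"]
        g = gamma if gamma is not None else GRANTHAM_WEIGHTS["gamma"]
        residues = tuple(sorted(props))
        n = len(residues)
        raw = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            ci, pi, vi = props[residues[i]]
            cj, pj, vj = props[residues[j]]
            d = math.sqrt(a * (ci - cj) ** 2 + b * (pi - pj) ** 2 + g * (vi - vj) ** 2)
            raw[i, j] = raw[j, i] = d
        pairs = raw[np.triu_indices(n, k=1)]
        scale = mean_target / pairs.mean()
        mat = raw * scale
        index = {r: i for i, r in enumerate(residues)}
        return cls(residues, mat, index)

    def distance(self, a: str, b: str) -> float:
        try:
            return float(self.matrix[self._index[a.upper()], self._index[b.upper()]])
        except KeyError as e:
            raise KeyError(f"unknown residue {e.args[0]!r}")

    def mean_heterotypic(self) -> float:
        n = len(self.residues)
        return float(self.matrix[np.triu_indices(n, k=1)].mean())


_DEFAULT_TABLE: GranthamTable | None = None


def default_grantham_table() -> GranthamTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = GranthamTable.from_properties()
    return _DEFAULT_TABLE


@dataclass(frozen=True)
class ResiduePositionSet:
    """Ordered 1-based alignment positions into the amino-acid alignment.

    Used to restrict the Grantham distance to a subset of residues, e.g. the
    22 positions predicted to line the odorant-binding pocket. The default
    (None everywhere it is accepted) means the whole ORF.
    """

    positions: tuple[int, ...]
    label: str = ""

    def __post_init__(self):
        if len(set(self.positions)) != len(self.positions):
            raise ValueError("positions must be unique")
        if any(p < 1 for p in self.positions):
            raise ValueError("positions are 1-based; all must be >= 1")


def grantham_distance(
    pair: CodingSequencePair,
    positions: ResiduePositionSet | Sequence[int] | None = None,
    table: GranthamTable | None = None,
) -> float:
    """Mean Grantham property distance over compared amino-acid positions.

    Positions where either residue is a gap are skipped (pairwise deletion);
    the mean (not the sum) keeps ORF-wide and binding-site-subset values on
    one scale. Returns 0 iff the residues are identical at every compared
    position.
    """
    table = table or default_grantham_table()
    n = min(len(pair.aa_a), len(pair.aa_b))
    if positions is None:
        idx = range(1, n + 1)
    else:
        idx = positions.positions if isinstance(positions, ResiduePositionSet) else positions
        for p in idx:
            if not (1 <= p <= n):
                raise ValueError(f"position {p} outside alignment bounds 1..{n}")
    values = []
    for p in idx:
        ra, rb = pair.aa_a[p - 1], pair.aa_b[p - 1]
        if ra == GAP or rb == GAP:
            continue
        values.append(table.distance(ra, rb))
    if not values:
        raise AlignmentError("all requested positions are gapped in one sequence")
    return float(np.mean(values))


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986) pairwise dN/dS
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _codon_site_fractions(codon: str) -> tuple[float, float, float]:
    """Fraction of synonymous single-base changes at each codon position.

    Mutations to stop codons are excluded from the per-position denominator;
    the synonymous + nonsynonymous fractions at each position still sum to 1,
    preserving S + N = 3 x (number of codons).
    """
    fracs = []
    for pos in range(3):
        syn = 0
        considered = 0
        for alt in NUCLEOTIDES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            considered += 1
            if CODON_TABLE[mutant] == CODON_TABLE[codon]:
                syn += 1
        fracs.append(syn / considered if considered else 0.0)
    return tuple(fracs)


@lru_cache(maxsize=None)
def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two sense codons.

    Codons differing at several positions are resolved by averaging over all
    orderings of the single-base steps; pathways crossing a stop codon are
    excluded, unless every pathway does, in which case all pathways count.
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(diff_pos):
        path = [codon_a]
        for pos in order:
            path.append(path[-1][:pos] + codon_b[pos] + path[-1][pos + 1 :])
        blocked = any(c in STOP_CODONS for c in path[1:])
        sd = nd = 0
        for prev, nxt in zip(path, path[1:]):
            if prev in STOP_CODONS or nxt in STOP_CODONS:
                continue  # only counted on the blocked-fallback branch
            if CODON_TABLE[nxt] == CODON_TABLE[prev]:
                sd += 1
            else:
                nd += 1
        pathways.append((sd, nd, blocked))
    open_paths = [(sd, nd) for sd, nd, blk in pathways if not blk]
    if not open_paths:
        # all pathways cross a stop: fall back to raw averages over all,
        # counting only the steps between sense codons
        open_paths = [(sd, nd) for sd, nd, _ in pathways]
    sd = float(np.mean([s for s, _ in open_paths]))
    nd = float(np.mean([n for _, n in open_paths]))
    return sd, nd


@dataclass(frozen=True)
class OmegaEstimate:
    """Nei-Gojobori site/difference counts and Jukes-Cantor-corrected rates.

    ``omega`` is NaN with ``omega_defined`` False when dS = 0 (the ratio has
    no information); saturation in either proportion is flagged per component
    rather than raised, so a table of pairs can carry partial results.
    """

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    omega: float
    omega_defined: bool
    dS_saturated: bool = False
    dN_saturated: bool = False


def nei_gojobori_omega(pair: CodingSequencePair) -> OmegaEstimate:
    """Pairwise dN/dS by the Nei-Gojobori (1986) unweighted-pathway method."""
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for ca, cb in pair.codon_pairs():
        n_codons += 1
        fa = _codon_site_fractions(ca)
        fb = _codon_site_fractions(cb)
        s_codon = (sum(fa) + sum(fb)) / 2.0
        S += s_codon
        N += 3.0 - s_codon
        sd, nd = _pathway_counts(ca, cb)
        Sd += sd
        Nd += nd
    if n_codons == 0:
        raise AlignmentError("zero comparable codons")
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0

    dS_saturated = pS >= 0.75
    dN_saturated = pN >= 0.75
    dS = float("nan") if dS_saturated else -0.75 * math.log1p(-4.0 * pS / 3.0)
    dN = float("nan") if dN_saturated else -0.75 * math.log1p(-4.0 * pN / 3.0)

    if dS_saturated or dN_saturated or dS == 0.0:
        omega, defined = float("nan"), False
    else:
        omega, defined = dN / dS, True
    return OmegaEstimate(S, N, Sd, Nd, pS, pN, dS, dN, omega, defined,
                         dS_saturated, dN_saturated)


# ---------------------------------------------------------------------------
# Neighbor-Joining
# ---------------------------------------------------------------------------

def neighbor_joining_tree(labels: Sequence[str], matrix: np.ndarray):
    """Neighbor-Joining tree from a symmetric distance matrix.

    Returns a scikit-bio ``TreeNode`` (serializable as Newick via ``str`` or
    ``tree.write``). The 2-taxon case, below the NJ recursion base, is a
    single edge carrying the full distance.
    """
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj

    matrix = np.asarray(matrix, dtype=float)
    if len(labels) < 2:
        raise ValueError("need at least 2 taxa")
    if matrix.shape != (len(labels), len(labels)):
        raise ValueError("matrix shape does not match labels")
    if not np.allclose(matrix, matrix.T):
        raise ValueError("distance matrix must be symmetric")
    if (matrix < 0).any():
        raise ValueError("distance matrix must be nonnegative")
    if len(labels) == 2:
        from skbio import TreeNode

        d = float(matrix[0, 1])
        root = TreeNode(name=None)
        a = TreeNode(name=labels[0], length=0.0)
        b = TreeNode(name=labels[1], length=d)
        root.extend([a, b])
        return root
    return nj(SkbioDM(matrix, ids=list(labels)))
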