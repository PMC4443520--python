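"""Sequence statistics for aligned haplotype data.

Implements the distance and diversity layer of the genetic analysis:
uncorrected p-distances with pairwise deletion of gaps and ambiguous
bases, haplotype and nucleotide diversity, AMOVA-based phi_ST with a
permutation test, a pseudogene screen for protein-coding loci under the
invertebrate mitochondrial code, neighbor-joining for visualization, and
single-linkage clade partitioning of a distance matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
import skbio

from .errors import ConfigurationError, InputError

__all__ = [
    "SequenceAlignment",
    "PopulationPartition",
    "DistanceMatrix",
    "DiversityStats",
    "PhiStResult",
    "p_distance_matrix",
    "haplotype_stats",
    "nucleotide_diversity",
    "phi_st",
    "pseudogene_check",
    "nj_tree",
    "clade_partition",
]

_BASES = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class SequenceAlignment:
    """Equal-length aligned sequences with unique specimen labels."""

    ids: list[str]
    seqs: list[str]
    locus: str = ""

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise InputError("ids and seqs must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise InputError("specimen ids must be unique")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise InputError(f"sequences are not aligned (lengths {sorted(lengths)})")
        self.seqs = [s.upper() for s in self.seqs]

    @property
    def n(self) -> int:
        return len(self.seqs)

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def to_matrix(self) -> np.ndarray:
        """(n, L) array of byte codes."""
        return np.frombuffer("".join(self.seqs).encode(), dtype="S1").reshape(
            self.n, self.length
        )


@dataclass
class PopulationPartition:
    """Mapping from specimen label to group (morphotype and/or region)."""

    mapping: dict[str, str]

    def groups_for(self, aln: SequenceAlignment) -> np.ndarray:
        missing = [i for i in self.mapping if i not in set(aln.ids)]
        if missing:
            raise InputError(f"partition labels absent from alignment: {missing}")
        return np.array([self.mapping[i] for i in aln.ids if i in self.mapping])

    def subset(self, aln: SequenceAlignment) -> SequenceAlignment:
        keep = [i for i, sid in enumerate(aln.ids) if sid in self.mapping]
        return SequenceAlignment(
            ids=[aln.ids[i] for i in keep],
            seqs=[aln.seqs[i] for i in keep],
            locus=aln.locus,
        )


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray  # proportion of differing sites
    effective_length: np.ndarray | None = None  # sites compared per pair

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


@dataclass
class DiversityStats:
    n: int
    n_haplotypes: int
    S: int
    H: float
    pi: float


@dataclass
class PhiStResult:
    phi_st: float
    p: float | None
    n_perm: int
    sigma2_among: float
    sigma2_within: float
    flagged_groups: list = field(default_factory=list)
    seed: int | None = None


# ---------------------------------------------------------------------------
# distances and diversity


def _valid_mask(aln: SequenceAlignment) -> tuple[np.ndarray, np.ndarray]:
    """Integer-coded matrix plus a mask of unambiguous A/C/G/T positions."""
    m = aln.to_matrix()
    codes = np.full(m.shape, -1, dtype=np.int8)
    for b, c in _BASES.items():
        codes[m == b.encode()] = c
    return codes, codes >= 0


def _pairwise_counts(aln: SequenceAlignment) -> tuple[np.ndarray, np.ndarray]:
    """(diff_counts, compared_counts) over all pairs, pairwise deletion."""
    codes, valid = _valid_mask(aln)
    n = aln.n
    diffs = np.zeros((n, n))
    comps = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        comps[i, i + 1 :] = both.sum(axis=1)
        diffs[i, i + 1 :] = ((codes[i] != codes[i + 1 :]) & both).sum(axis=1)
    diffs += diffs.T
    comps += comps.T
    return diffs, comps


def p_distance_matrix(aln: SequenceAlignment) -> DistanceMatrix:
    """Uncorrected p-distances with pairwise deletion of gaps/ambiguity."""
    if aln.n < 2:
        raise InputError("need at least 2 sequences")
    diffs, comps = _pairwise_counts(aln)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(comps > 0, diffs / np.maximum(comps, 1), np.nan)
    np.fill_diagonal(d, 0.0)
    if np.isnan(d).any():
        warnings.warn("some pairs share no comparable sites (NaN distances)", stacklevel=2)
    return DistanceMatrix(labels=list(aln.ids), matrix=d, effective_length=comps)


def haplotype_stats(aln: SequenceAlignment, ignore_ambiguous: bool = False) -> DiversityStats:
    """Haplotype count, segregating sites, and haplotype diversity H.

    Haplotypes are distinct full-length strings; S counts columns with at
    least two distinct unambiguous bases; H uses the n/(n-1) correction.
    With ``ignore_ambiguous`` every column containing a gap or ambiguity
    code in any sequence is dropped before haplotypes are compared, so
    sequences differing only at such columns collapse.
    """
    if aln.n < 2:
        raise InputError("need at least 2 sequences")
    n = aln.n
    hap_seqs = aln.seqs
    if ignore_ambiguous:
        _, valid = _valid_mask(aln)
        keep = np.flatnonzero(valid.all(axis=0))
        hap_seqs = ["".join(s[j] for j in keep) for s in aln.seqs]
    haps = pd.Series(hap_seqs).value_counts()
    freqs = haps.to_numpy() / n
    H = n / (n - 1) * (1.0 - float((freqs**2).sum()))
    codes, valid = _valid_mask(aln)
    S = 0
    for j in range(aln.length):
        col = codes[valid[:, j], j]
        if len(np.unique(col)) >= 2:
            S += 1
    return DiversityStats(
        n=n, n_haplotypes=len(haps), S=S, H=H, pi=nucleotide_diversity(aln)
    )


def nucleotide_diversity(aln: SequenceAlignment) -> float:
    """pi: mean pairwise per-site p-distance over all sequence pairs."""
    d = p_distance_matrix(aln).matrix
    n = len(d)
    iu = np.triu_indices(n, 1)
    return float(np.nanmean(d[iu]))


# ---------------------------------------------------------------------------
# AMOVA phi_ST


def _phi_from_delta(delta: np.ndarray, codes: np.ndarray, sizes: np.ndarray):
    """phi_ST from a matrix of pairwise difference counts and group codes."""
    n = len(codes)
    G = len(sizes)
    ssd_total = delta.sum() / (2.0 * n)
    ssd_within = 0.0
    for g in range(G):
        m = codes == g
        ssd_within += delta[np.ix_(m, m)].sum() / (2.0 * sizes[g])
    ssd_among = ssd_total - ssd_within
    sigma2_within = ssd_within / (n - G)
    n_bar = (n - (sizes**2).sum() / n) / (G - 1)
    sigma2_among = (ssd_among / (G - 1) - sigma2_within) / n_bar
    denom = sigma2_among + sigma2_within
    phi = sigma2_among / denom if denom != 0 else 0.0
    return phi, sigma2_among, sigma2_within


def phi_st(
    aln: SequenceAlignment,
    part: PopulationPartition,
    n_perm: int = 10000,
    seed: int | None = None,
) -> PhiStResult:
    """AMOVA fixation index phi_ST based on pairwise differences.

    The molecular variance is partitioned using raw pairwise difference
    counts as squared distances; significance is assessed by permuting
    individuals among groups with group sizes fixed (+1 convention).
    """
    sub = part.subset(aln)
    groups = part.groups_for(aln)
    codes, uniques = pd.factorize(groups)
    G = len(uniques)
    if G < 2:
        raise InputError("phi_ST needs at least 2 groups")
    if sub.n < 4:
        raise InputError("phi_ST needs at least 4 sequences in total")
    sizes = np.bincount(codes).astype(float)
    flagged = [str(uniques[g]) for g in range(G) if sizes[g] < 2]
    if flagged:
        warnings.warn(f"groups of size 1: {flagged}", stacklevel=2)
    delta, _ = _pairwise_counts(sub)
    if delta.sum() == 0.0:
        warnings.warn("all sequences identical; phi_ST set to 0", stacklevel=2)
        return PhiStResult(0.0, None, 0, 0.0, 0.0, flagged, seed)
    phi_obs, s2a, s2w = _phi_from_delta(delta, codes, sizes)
    p = None
    if n_perm >= 1:
        rng = np.random.default_rng(seed)
        n = len(codes)
        perms = np.argsort(rng.random((n_perm, n)), axis=1)
        perm_codes = codes[perms]  # (n_perm, n); group sizes preserved
        ssd_total = delta.sum() / (2.0 * n)
        ssw = np.zeros(n_perm)
        for g in range(G):
            m = (perm_codes == g).astype(float)
            ssw += np.einsum("pi,ij,pj->p", m, delta, m) / (2.0 * sizes[g])
        s2w_perm = ssw / (n - G)
        n_bar = (n - (sizes**2).sum() / n) / (G - 1)
        s2a_perm = ((ssd_total - ssw) / (G - 1) - s2w_perm) / n_bar
        denom = s2a_perm + s2w_perm
        with np.errstate(invalid="ignore", divide="ignore"):
            phi_perm = np.where(denom != 0, s2a_perm / denom, 0.0)
        p = float((1 + np.sum(phi_perm >= phi_obs)) / (n_perm + 1))
    return PhiStResult(float(phi_obs), p, n_perm, float(s2a), float(s2w), flagged, seed)


# ---------------------------------------------------------------------------
# pseudogene screen


def pseudogene_check(
    aln: SequenceAlignment, genetic_code: str = "invert-mito", frame: int = 0
) -> pd.DataFrame:
    """Screen a protein-coding alignment for stop codons and indels.

    A sequence passes when it contains no internal stop codon in the
    requested reading frame (a terminal stop in the final complete codon
    is tolerated) and no gap characters. Codon semantics follow the
    named NCBI translation table; the invertebrate mitochondrial code
    (table 5) notably reads AGA/AGG as serine, not stop.
    """
    tables = {"invert-mito": 5, "standard": 1, "vert-mito": 2}
    if genetic_code not in tables:
        raise ConfigurationError(
            f"unknown genetic code {genetic_code!r}; choose from {sorted(tables)}"
        )
    if frame not in (0, 1, 2):
        raise ConfigurationError("frame must be 0, 1 or 2")
    stops = set(CodonTable.unambiguous_dna_by_id[tables[genetic_code]].stop_codons)
    rows = []
    for sid, seq in zip(aln.ids, aln.seqs):
        gaps = seq.count("-")
        coding = seq[frame:]
        n_codons = len(coding) // 3
        codons = [coding[3 * i : 3 * i + 3] for i in range(n_codons)]
        internal = sum(1 for c in codons[:-1] if c in stops)
        rows.append(
            {
                "id": sid,
                "internal_stops": internal,
                "gaps": gaps,
                "passes": internal == 0 and gaps == 0,
            }
        )
    return pd.DataFrame(rows).set_index("id")


# ---------------------------------------------------------------------------
# trees and clade partitioning


def nj_tree(dm: DistanceMatrix) -> str:
    """Neighbor-joining tree (Newick) with branch lengths clipped at 0."""
    if len(dm.labels) < 3:
        raise InputError("NJ needs at least 3 taxa")
    if np.isnan(dm.matrix).any():
        raise InputError("distance matrix contains undefined entries")
    order = np.argsort(np.asarray(dm.labels, dtype=object))
    labels = [dm.labels[i] for i in order]
    mat = dm.matrix[np.ix_(order, order)]
    sk_dm = skbio.DistanceMatrix(mat, ids=labels)
    tree = skbio.tree.nj(sk_dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return str(tree).strip()


def clade_partition(dm: DistanceMatrix, threshold: float) -> pd.Series:
    """Single-linkage clusters: connected components of the d < threshold graph."""
    if threshold <= 0:
        raise InputError("threshold must be positive")
    adj = (dm.matrix < threshold).astype(np.int8)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    return pd.Series(labels, index=dm.labels, name="clade")
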