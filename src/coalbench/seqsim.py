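"""Sequence simulation under HKY with continuous gamma rate heterogeneity.

Alignments evolve along a gene tree under a strict clock: the root sequence
is drawn from the stationary base frequencies and every branch applies the
exact HKY transition-probability matrix, with an i.i.d. Gamma(alpha, mean 1)
rate multiplier per site shared across all branches.  Transition
probabilities come from the closed-form HKY spectral decomposition, not a
numerical matrix exponential.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDES = "ACGT"
_CODE = {c: i for i, c in enumerate(NUCLEOTIDES)}

__all__ = [
    "SubstitutionModel",
    "STUDY_MODEL",
    "kappa_from_tstv",
    "hky_rate_matrix",
    "hky_transition_probs",
    "hky_transition_probs_params",
    "simulate_alignment",
    "Alignment",
]


@dataclass(frozen=True)
class SubstitutionModel:
    """HKY+Gamma substitution model parameters.

    Parameters
    ----------
    base_freqs : stationary frequencies in A, C, G, T order (sum to 1).
    tstv_ratio : expected transition/transversion *ratio* (not kappa); the
        rate-matrix kappa is derived from it and the base frequencies.
    gamma_shape : shape of the mean-1 gamma distribution of site rates;
        ``None`` disables rate heterogeneity.
    subst_scale : expected substitutions per site per coalescent unit, used
        to convert coalescent branch lengths to substitution branch lengths.
    """

    base_freqs: tuple = (0.25, 0.25, 0.25, 0.25)
    tstv_ratio: float = 3.0
    gamma_shape: float | None = 0.8
    subst_scale: float = 0.05

    def __post_init__(self):
        freqs = np.asarray(self.base_freqs, dtype=float)
        if freqs.shape != (4,) or np.any(freqs <= 0):
            raise ValueError("base_freqs must be 4 positive numbers (A,C,G,T)")
        if abs(freqs.sum() - 1.0) > 1e-12:
            raise ValueError(f"base_freqs must sum to 1, got {freqs.sum()!r}")
        if not self.tstv_ratio > 0:
            raise ValueError("tstv_ratio must be > 0")
        if self.gamma_shape is not None and not self.gamma_shape > 0:
            raise ValueError("gamma_shape must be > 0 or None")
        if not self.subst_scale > 0:
            raise ValueError("subst_scale must be > 0")
        object.__setattr__(self, "base_freqs", tuple(float(f) for f in freqs))

    @property
    def kappa(self) -> float:
        return kappa_from_tstv(self.tstv_ratio, self.base_freqs)

    @property
    def freqs(self) -> np.ndarray:
        return np.asarray(self.base_freqs)


#: Model used throughout the benchmark: HKY, ts/tv 3.0, Gamma shape 0.8,
#: frequencies A=0.3, C=0.2, G=0.2, T=0.3, 0.05 substitutions/site per
#: coalescent unit.
STUDY_MODEL = SubstitutionModel(base_freqs=(0.3, 0.2, 0.2, 0.3))


def kappa_from_tstv(tstv_ratio: float, base_freqs) -> float:
    """Convert an expected ts/tv ratio to the HKY rate-matrix kappa.

    At stationarity the transition flux is proportional to
    ``kappa (pA pG + pC pT)`` and the transversion flux to
    ``(pA + pG)(pC + pT)``, so ``kappa = R (pA+pG)(pC+pT) / (pA pG + pC pT)``.
    """
    pa, pc, pg, pt = base_freqs
    return tstv_ratio * (pa + pg) * (pc + pt) / (pa * pg + pc * pt)


def _beta(model: SubstitutionModel) -> float:
    """Rate-matrix normalizer so the expected rate at stationarity is 1."""
    pa, pc, pg, pt = model.base_freqs
    kappa = model.kappa
    return 1.0 / (2.0 * ((pa + pg) * (pc + pt) + kappa * (pa * pg + pc * pt)))


def hky_rate_matrix(model: SubstitutionModel) -> np.ndarray:
    """HKY instantaneous rate matrix Q (A,C,G,T order), mean rate 1."""
    pi = model.freqs
    kappa = model.kappa
    beta = _beta(model)
    transition = np.zeros((4, 4), dtype=bool)
    transition[_CODE["A"], _CODE["G"]] = transition[_CODE["G"], _CODE["A"]] = True
    transition[_CODE["C"], _CODE["T"]] = transition[_CODE["T"], _CODE["C"]] = True
    q = beta * np.tile(pi, (4, 1))
    q[transition] *= kappa
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def hky_transition_probs(model: SubstitutionModel, t) -> np.ndarray:
    """Exact HKY transition-probability matrices ``P(t)``.

    ``t`` is an array (any shape) of branch lengths in expected
    substitutions per site; the result has shape ``t.shape + (4, 4)``.
    Uses the closed-form spectral decomposition of the HKY generator.
    """
    return hky_transition_probs_params(model.freqs, model.kappa, t)


def hky_transition_probs_params(pi, kappa: float, t) -> np.ndarray:
    """Closed-form HKY ``P(t)`` from explicit frequencies and kappa.

    The generator is normalized to one expected substitution per site per
    unit branch length, matching :func:`hky_rate_matrix`.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)) or np.any(t < 0):
        raise ValueError("branch lengths must be finite and non-negative")
    pi = np.asarray(pi, dtype=float)
    pa, pc, pg, pt = pi
    beta = 1.0 / (2.0 * ((pa + pg) * (pc + pt) + kappa * (pa * pg + pc * pt)))
    pr, py = pa + pg, pc + pt
    group = np.array([pr, py, pr, py])  # frequency of j's purine/pyrimidine group

    e1 = np.exp(-beta * t)[..., None, None]
    # group-specific second eigenvalue: -beta (group * kappa + (1 - group))
    rate2 = beta * (group * kappa + (1.0 - group))
    e2 = np.exp(-t[..., None] * rate2)[..., None, :]  # varies with column j

    pij = np.broadcast_to(pi, (4, 4))
    grp = np.broadcast_to(group, (4, 4))
    same_group = np.array(
        [[i % 2 == j % 2 for j in range(4)] for i in range(4)]
    )  # A,G at even indices? A=0,C=1,G=2,T=3 -> purines at 0,2
    eye = np.eye(4, dtype=bool)

    p = np.empty(t.shape + (4, 4))
    # transversions
    p[...] = pij * (1.0 - e1)
    # transitions (same group, off-diagonal)
    trans = same_group & ~eye
    p_trans = pij + pij * ((1.0 - grp) / grp) * e1 - (pij / grp) * e2
    p_diag = pij + pij * ((1.0 - grp) / grp) * e1 + ((grp - pij) / grp) * e2
    p[..., trans] = p_trans[..., trans]
    p[..., eye] = p_diag[..., eye]
    return p


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """Gap-free nucleotide alignment: taxon labels plus a coded matrix.

    ``codes`` holds rows of integers 0..3 in A,C,G,T order, one row per
    taxon, all of identical length.
    """

    taxa: tuple
    codes: np.ndarray

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.taxa):
            raise ValueError("codes must be a (n_taxa, length) matrix")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxon labels must be unique")
        if self.codes.size and self.codes.max() > 3:
            raise ValueError("codes must be in 0..3 (A,C,G,T)")
        self.taxa = tuple(self.taxa)

    @property
    def length(self) -> int:
        return self.codes.shape[1]

    def sequence(self, taxon: str) -> str:
        row = self.codes[self.taxa.index(taxon)]
        return "".join(NUCLEOTIDES[c] for c in row)

    def to_biopython(self) -> MultipleSeqAlignment:
        return MultipleSeqAlignment(
            SeqRecord(Seq(self.sequence(t)), id=t, description="") for t in self.taxa
        )

    def write(self, path, schema: str = "fasta") -> None:
        """Write as 'fasta', 'phylip-relaxed', or 'nexus'."""
        msa = self.to_biopython()
        if schema == "nexus":
            for rec in msa:
                rec.annotations["molecule_type"] = "DNA"
        AlignIO.write(msa, str(path), schema)

    @classmethod
    def read(cls, path, schema: str = "fasta") -> "Alignment":
        msa = AlignIO.read(str(path), schema)
        taxa = tuple(rec.id for rec in msa)
        codes = np.array(
            [[_CODE[c] for c in str(rec.seq).upper()] for rec in msa], dtype=np.uint8
        )
        return cls(taxa, codes)

    @classmethod
    def from_sequences(cls, mapping: dict) -> "Alignment":
        taxa = tuple(mapping)
        codes = np.array(
            [[_CODE[c] for c in seq.upper()] for seq in mapping.values()], dtype=np.uint8
        )
        return cls(taxa, codes)


def concatenate(alignments) -> tuple:
    """Column-wise concatenation; returns (Alignment, partition table).

    The partition table is a list of ``(name, start, end)`` with 1-based
    inclusive coordinates.  All alignments must share one taxon set; rows
    are matched by label.
    """
    alignments = list(alignments)
    if not alignments:
        raise ValueError("need at least one alignment")
    taxa = tuple(sorted(alignments[0].taxa))
    blocks, partition, pos = [], [], 0
    for i, aln in enumerate(alignments):
        if tuple(sorted(aln.taxa)) != taxa:
            raise ValueError("taxon sets differ among alignments")
        order = [aln.taxa.index(t) for t in taxa]
        blocks.append(aln.codes[order])
        partition.append((f"locus_{i + 1}", pos + 1, pos + aln.length))
        pos += aln.length
    return Alignment(taxa, np.concatenate(blocks, axis=1)), partition


def simulate_alignment(
    tree: dendropy.Tree,
    length: int,
    model: SubstitutionModel,
    rng: np.random.Generator,
    branch_lengths_in_substitutions: bool = False,
) -> Alignment:
    """Simulate a ``length``-column alignment along ``tree`` under HKY+Gamma.

    Branch lengths are taken as coalescent units and multiplied by
    ``model.subst_scale`` unless ``branch_lengths_in_substitutions`` is set.
    Site rates are continuous Gamma(shape, mean 1) draws shared across
    branches (a strict clock with among-site rate variation only).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and not np.isfinite(edge.length):
            raise ValueError("non-finite branch length in tree")

    scale = 1.0 if branch_lengths_in_substitutions else model.subst_scale
    if model.gamma_shape is None:
        rates = np.ones(length)
    else:
        rates = rng.gamma(shape=model.gamma_shape, scale=1.0 / model.gamma_shape, size=length)

    pi = model.freqs
    states = {}
    root = tree.seed_node
    states[root] = rng.choice(4, size=length, p=pi)
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        t_eff = (node.edge.length or 0.0) * scale * rates
        pmats = hky_transition_probs(model, t_eff)  # (L, 4, 4)
        rows = pmats[np.arange(length), states[node.parent_node]]  # (L, 4)
        u = rng.random(length)
        states[node] = (rows.cumsum(axis=1) < u[:, None]).sum(axis=1).astype(np.uint8)

    taxa, codes = [], []
    for leaf in tree.leaf_node_iter():
        taxa.append(leaf.taxon.label)
        codes.append(states[leaf])
    order = np.argsort(taxa)
    return Alignment(tuple(taxa[i] for i in order), np.array(codes)[order])
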