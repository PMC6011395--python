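"""Mutation spectra, Kullback-Leibler comparison and signature ranking.

Single-base substitutions are tabulated in the standard 96-context
space: six pyrimidine-strand substitution classes (C>A, C>G, C>T, T>A,
T>C, T>G) by 5' and 3' flanking base.  Purine-reference substitutions
are reverse-complemented onto the pyrimidine strand together with their
context.  Spectra are compared by (optionally symmetrized) KL
divergence with a small pseudocount, clustered agglomeratively, and
ranked against a catalog of reference signatures by cosine similarity
or KL.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.special import rel_entr

from .genome import GenomeAssembly, reverse_complement
from .variants import VariantRecord

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"

#: Canonical ordering of the 96 trinucleotide contexts: class-major,
#: then 5' base, then 3' base (e.g. "A[C>A]A", "A[C>A]C", ...).
CONTEXT_LABELS: Tuple[str, ...] = tuple(
    f"{five}[{cls}]{three}"
    for cls in SUBSTITUTION_CLASSES
    for five in _BASES
    for three in _BASES
)

_CONTEXT_INDEX = {label: i for i, label in enumerate(CONTEXT_LABELS)}


def context_index(cls: str, five: str, three: str) -> int:
    return _CONTEXT_INDEX[f"{five}[{cls}]{three}"]


def pyrimidine_context(ref: str, alt: str, five: str, three: str) -> Tuple[str, str, str]:
    """Collapse a substitution + context onto the pyrimidine strand.

    Returns (class, 5' base, 3' base).  Purine references (A/G) are
    reverse-complemented, which also swaps and complements the flanks.
    """
    if ref in "AG":
        ref, alt = reverse_complement(ref), reverse_complement(alt)
        five, three = reverse_complement(three), reverse_complement(five)
    return f"{ref}>{alt}", five, three


@dataclass
class MutationSpectrum:
    """96-context substitution counts for one sample."""

    sample_id: str
    counts: np.ndarray = field(default_factory=lambda: np.zeros(96, dtype=np.int64))
    skipped_non_snv: int = 0
    skipped_ambiguous_context: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (96,):
            raise ValueError("counts must be a 96-vector")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        t = self.total
        if t == 0:
            return np.zeros(96, dtype=float)
        return self.counts / t

    @property
    def collapsed6(self) -> Dict[str, float]:
        """Marginal frequency per substitution class."""
        freq = self.frequencies
        return {
            cls: float(freq[i * 16 : (i + 1) * 16].sum())
            for i, cls in enumerate(SUBSTITUTION_CLASSES)
        }

    def add(self, cls: str, five: str, three: str, n: int = 1) -> None:
        self.counts[context_index(cls, five, three)] += n


def build_spectrum(
    snvs: Sequence[VariantRecord],
    genome: GenomeAssembly,
    sample_id: str = "sample",
) -> MutationSpectrum:
    """Tabulate SNVs into a 96-context spectrum.

    Non-SNVs and SNVs whose trinucleotide context is unavailable
    (chromosome edge or an N in the context) are skipped and counted.
    """
    spec = MutationSpectrum(sample_id=sample_id)
    for rec in snvs:
        if rec.kind != "SNV":
            spec.skipped_non_snv += 1
            continue
        pos0 = rec.pos - 1
        chrom_len = genome.length(rec.chrom)
        if pos0 - 1 < 0 or pos0 + 2 > chrom_len:
            spec.skipped_ambiguous_context += 1
            continue
        tri = genome.fetch(rec.chrom, pos0 - 1, pos0 + 2)
        if "N" in tri or rec.ref == "N" or rec.alt == "N":
            spec.skipped_ambiguous_context += 1
            continue
        if tri[1] != rec.ref:
            raise ValueError(
                f"reference mismatch at {rec.chrom}:{rec.pos}: genome has "
                f"{tri[1]}, record ref is {rec.ref}"
            )
        cls, five, three = pyrimidine_context(rec.ref, rec.alt, tri[0], tri[2])
        spec.add(cls, five, three)
    return spec


# ---------------------------------------------------------------------------
# Divergence


def kl_divergence(
    p: np.ndarray,
    q: np.ndarray,
    pseudocount: float = 1e-6,
    symmetrized: bool = True,
) -> float:
    """KL divergence (nats) between two frequency vectors.

    A pseudocount is added to every cell and the vectors renormalized,
    so the divergence is finite on sparse spectra.  The symmetrized
    variant averages both directions.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {q.shape}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    ps = p + pseudocount
    qs = q + pseudocount
    ps = ps / ps.sum()
    qs = qs / qs.sum()
    forward = float(rel_entr(ps, qs).sum())
    if not symmetrized:
        return forward
    backward = float(rel_entr(qs, ps).sum())
    return 0.5 * (forward + backward)


def distance_matrix(
    spectra: Sequence[MutationSpectrum],
    pseudocount: float = 1e-6,
) -> pd.DataFrame:
    """Pairwise symmetrized-KL matrix, samples sorted by id."""
    ordered = sorted(spectra, key=lambda s: s.sample_id)
    ids = [s.sample_id for s in ordered]
    n = len(ordered)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = kl_divergence(
                ordered[i].frequencies, ordered[j].frequencies,
                pseudocount=pseudocount, symmetrized=True,
            )
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# Clustering


@dataclass
class Dendrogram:
    """Agglomerative merge tree over samples."""

    labels: List[str]
    linkage_matrix: np.ndarray

    def cut(self, k: int) -> Dict[str, int]:
        """Flat clustering into k groups: sample id -> cluster label."""
        assignment = hierarchy.fcluster(self.linkage_matrix, k, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assignment)))

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage_matrix)

        def walk(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            children = ",".join(walk(c, node.dist) for c in (node.left, node.right))
            return f"({children}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def cluster_samples(
    spectra: Sequence[MutationSpectrum],
    linkage: str = "average",
    pseudocount: float = 1e-6,
) -> Tuple[Dendrogram, pd.DataFrame]:
    """Hierarchical clustering on the symmetrized-KL matrix.

    Samples are ordered lexicographically by id before linkage, which
    makes tie-breaking deterministic and input-order invariant.
    """
    if len(spectra) < 2:
        raise ValueError("clustering needs at least 2 spectra")
    if linkage not in ("average", "complete"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    dm = distance_matrix(spectra, pseudocount=pseudocount)
    condensed = squareform(dm.values, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    return Dendrogram(labels=list(dm.index), linkage_matrix=Z), dm


# ---------------------------------------------------------------------------
# Signature catalog and ranking


@dataclass
class SignatureCatalog:
    """Named reference signatures: 96-vectors of probabilities."""

    signatures: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name, vec in self.signatures.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (96,):
                raise ValueError(f"signature {name!r} is not a 96-vector")
            if abs(vec.sum() - 1.0) > 1e-6:
                raise ValueError(f"signature {name!r} does not sum to 1")
            self.signatures[name] = vec

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SignatureCatalog":
        """96 rows x signature columns; first column holds context labels."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        df = df.loc[list(CONTEXT_LABELS)]
        return cls({name: df[name].to_numpy(dtype=float) for name in df.columns})

    def write_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.signatures, index=list(CONTEXT_LABELS))
        df.index.name = "context"
        df.to_csv(path, sep="\t")


def rank_signatures(
    spectrum: MutationSpectrum,
    catalog: SignatureCatalog,
    metric: str = "cosine",
    pseudocount: float = 1e-6,
) -> List[Tuple[str, float]]:
    """Rank catalog signatures by similarity to a spectrum.

    Cosine similarity is ranked descending; symmetrized KL ascending.
    Ties break lexicographically by signature name.
    """
    if not catalog.signatures:
        raise ValueError("empty signature catalog")
    freq = spectrum.frequencies
    if freq.sum() == 0:
        raise ValueError("cannot rank a zero spectrum")
    scores: List[Tuple[str, float]] = []
    for name in sorted(catalog.signatures):
        sig = catalog.signatures[name]
        if metric == "cosine":
            denom = np.linalg.norm(freq) * np.linalg.norm(sig)
            score = float(freq @ sig / denom) if denom else 0.0
        elif metric == "kl":
            score = kl_divergence(freq, sig, pseudocount=pseudocount, symmetrized=True)
        else:
            raise ValueError(f"unknown metric {metric!r}")
        scores.append((name, score))
    reverse = metric == "cosine"
    return sorted(scores, key=lambda t: (-t[1] if reverse else t[1], t[0]))


# ---------------------------------------------------------------------------
# I/O


def write_spectrum_tsv(spectra: Sequence[MutationSpectrum], path: str | Path) -> None:
    df = pd.DataFrame(
        {s.sample_id: s.counts for s in spectra}, index=list(CONTEXT_LABELS)
    )
    df.index.name = "context"
    df.to_csv(path, sep="\t")


def read_spectrum_tsv(path: str | Path) -> List[MutationSpectrum]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = df.loc[list(CONTEXT_LABELS)]
    return [
        MutationSpectrum(sample_id=col, counts=df[col].to_numpy(dtype=np.int64))
        for col in df.columns
    ]


def write_distance_matrix_tsv(dm: pd.DataFrame, path: str | Path) -> None:
    dm.to_csv(path, sep="\t")


def write_ranking_tsv(ranking: Sequence[Tuple[str, float]], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["signature", "score"])
        for name, score in ranking:
            w.writerow([name, f"{score:.6f}"])
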