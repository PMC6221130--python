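"""Split-half instrument weights and (nontransmitted) allele scores.

Per-SNP weights are the slopes of simple regressions of the exposure on each
instrument SNP, fitted in the training half (A) of the trio dataset; scores
are then built in the analysis half (B) to avoid overfitting the instrument.
A score is the weighted sum of effect-allele counts; the nontransmitted score
applies the same weights to the parental alleles that were *not* passed to
the offspring, which makes it a genetic instrument for the parental phenotype
that is independent of the offspring genotype given the parents.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .sim_population import TrioDataset

__all__ = [
    "AlleleScoreWeights",
    "ScoreSet",
    "estimate_weights",
    "build_scores",
    "infer_nontransmitted",
]


@dataclass
class AlleleScoreWeights:
    """Per-SNP instrument weights (phenotype units per effect allele)."""

    snp_idx: np.ndarray  # column indices into the trio genotype matrix
    weights: np.ndarray  # one finite weight per SNP
    trained_on: Optional[str] = None  # "A", "B", or None for external weights

    def __post_init__(self):
        self.snp_idx = np.asarray(self.snp_idx, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.snp_idx.shape != self.weights.shape:
            raise ValueError("one weight per instrument SNP required")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"snp_id": self.snp_idx, "weight": self.weights})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AlleleScoreWeights":
        return cls(snp_idx=df["snp_id"].to_numpy(),
                   weights=df["weight"].to_numpy(), trained_on=None)


@dataclass
class ScoreSet:
    """Weighted allele scores for the analysis half of a trio dataset."""

    rows: np.ndarray  # row indices into the trio dataset (analysis half)
    s: np.ndarray  # offspring score
    s_m: np.ndarray  # mother score
    s_f: np.ndarray  # father score
    w_m: np.ndarray  # mother nontransmitted score
    w_f: np.ndarray  # father nontransmitted score

    def __post_init__(self):
        for name in ("s", "s_m", "s_f", "w_m", "w_f"):
            v = getattr(self, name)
            if v.shape != self.rows.shape:
                raise ValueError(f"{name} must align with rows")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} contains non-finite values")


def _marginal_slopes(g: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Simple-regression slopes of x on each genotype column (vectorized)."""
    gc = g - g.mean(axis=0)
    xc = x - x.mean()
    var = np.einsum("ij,ij->j", gc, gc)
    cov = gc.T @ xc
    with np.errstate(invalid="ignore", divide="ignore"):
        slopes = cov / var
    return slopes, var


def estimate_weights(trios: TrioDataset, instrument_snps: Optional[Sequence[int]] = None,
                     half: str = "A") -> AlleleScoreWeights:
    """Per-SNP weights from regressing offspring X on each SNP in the training half.

    Monomorphic SNPs have an undefined slope; their weight is set to 0 with a
    warning so the score stays defined.
    """
    if instrument_snps is None:
        if trios.instrument_snps is None:
            raise ValueError("instrument_snps not given and not recorded in the dataset")
        instrument_snps = trios.instrument_snps
    snp_idx = np.asarray(instrument_snps, dtype=int)
    rows = trios.half(half)
    if rows.size == 0:
        raise ValueError(f"training half {half!r} is empty")
    g = trios.g_o[np.ix_(rows, snp_idx)].astype(float)
    slopes, var = _marginal_slopes(g, trios.x[rows])
    mono = var == 0
    if mono.any():
        warnings.warn(f"{int(mono.sum())} monomorphic SNP(s) in training half; "
                      "weight set to 0", RuntimeWarning)
        slopes = np.where(mono, 0.0, slopes)
    return AlleleScoreWeights(snp_idx=snp_idx, weights=slopes, trained_on=half)


def build_scores(trios: TrioDataset, weights: AlleleScoreWeights,
                 half: str = "B", allow_same_half: bool = False) -> ScoreSet:
    """Weighted allele scores S, S^m, S^f and nontransmitted scores W^m, W^f.

    Refuses to score the half the weights were trained on unless
    ``allow_same_half`` is set (overfitting guard).  Weights with
    ``trained_on=None`` (external, e.g. published GWAS weights) may be applied
    to the full sample by passing ``half="all"``.
    """
    if weights.trained_on is not None and weights.trained_on == half and not allow_same_half:
        raise ValueError(
            f"weights were trained on half {half!r}; scoring the same half "
            "overfits the instrument (pass allow_same_half=True to override)")
    if half == "all":
        rows = np.arange(trios.n_trios)
    else:
        rows = trios.half(half)
    idx = weights.snp_idx
    w = weights.weights

    def score(mat: np.ndarray) -> np.ndarray:
        return mat[np.ix_(rows, idx)].astype(float) @ w

    return ScoreSet(rows=rows, s=score(trios.g_o), s_m=score(trios.g_m),
                    s_f=score(trios.g_f), w_m=score(trios.nt_m),
                    w_f=score(trios.nt_f))


def infer_nontransmitted(g_o: np.ndarray, g_m: np.ndarray, g_f: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Infer per-SNP nontransmitted parental allele counts from unphased trios.

    Rules, per SNP and parent (counts are effect-allele dosages 0/1/2, the
    nontransmitted haplotype count is 0 or 1, fractional when ambiguous):

    * parent homozygous -> the nontransmitted allele equals either copy;
    * parent heterozygous, offspring homozygous -> transmitted allele is the
      offspring's allele, nontransmitted is the other;
    * parent heterozygous, offspring heterozygous, other parent homozygous ->
      the other parent's transmission is forced, this parent's follows by
      subtraction;
    * both parents heterozygous and offspring heterozygous -> ambiguous; the
      expected value 0.5 is used.

    Returns (nt_m, nt_f, ambiguous) where ``ambiguous`` is the per-trio count
    of unresolved parent-SNP combinations.
    """
    g_o = np.asarray(g_o, dtype=float)
    g_m = np.asarray(g_m, dtype=float)
    g_f = np.asarray(g_f, dtype=float)

    def one_parent(gp: np.ndarray, gq: np.ndarray):
        """Nontransmitted count for parent with genotype gp (other parent gq)."""
        nt = np.empty_like(gp)
        amb = np.zeros(gp.shape, dtype=bool)
        hom = gp != 1
        nt[hom] = gp[hom] / 2  # 0 or 1
        het = ~hom
        # parent het: transmitted = offspring dosage minus the other parent's
        # transmitted allele, when that is determined
        off_hom = (g_o == 0) | (g_o == 2)
        m = het & off_hom
        nt[m] = 1 - g_o[m] / 2
        q_hom = gq != 1
        m = het & ~off_hom & q_hom
        # other parent transmits gq/2, so this parent transmitted g_o - gq/2
        nt[m] = 1 - (g_o[m] - gq[m] / 2)
        m = het & ~off_hom & ~q_hom
        nt[m] = 0.5
        amb[m] = True
        return nt, amb

    nt_m, amb_m = one_parent(g_m, g_f)
    nt_f, amb_f = one_parent(g_f, g_m)
    ambiguous = (amb_m | amb_f).sum(axis=1)
    return nt_m, nt_f, ambiguous
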