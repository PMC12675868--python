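"""Model-based homozygosity-by-descent (HBD) classification.

A hidden Markov model describes each genome as a mosaic of HBD and non-HBD
segments.  There are K HBD classes plus one non-HBD class; segment lengths
in class k are exponential with rate R_k (Morgans^-1), layered as R_k = 2^k
by default, the non-HBD class sharing the last rate.  Over a map distance d
the chain stays inside its current class-k segment with probability
exp(-R_k d); on segment end the next segment's class is drawn from the
mixing distribution.  Emissions are Hardy-Weinberg genotype probabilities in
the non-HBD state and {freq_a, 0, freq_b} under HBD, convolved with a
symmetric genotyping-error kernel.  Forward-backward posteriors give the
per-locus HBD probability; F_HBD is its mean over loci.  Mixing coefficients
are re-estimated per animal by EM with the rates held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix
from .roh_detection import _chrom_slices

MORGAN_PER_BP_DEFAULT = 1e-8  # 1 cM/Mb


@dataclass
class HbdModel:
    n_classes: int = 10
    rates: np.ndarray | None = None  # length K; default 2^k, k = 1..K
    mixing: np.ndarray | None = None  # length K+1, sums to 1
    error_rate: float = 1e-3
    allele_freqs: np.ndarray | None = None  # per-SNP frequency of allele B

    def __post_init__(self):
        if self.rates is None:
            self.rates = 2.0 ** np.arange(1, self.n_classes + 1)
        self.rates = np.asarray(self.rates, dtype=float)
        if (np.diff(self.rates) <= 0).any():
            raise ValueError("rates must be strictly increasing")
        if self.mixing is None:
            self.mixing = np.full(self.n_classes + 1,
                                  1.0 / (self.n_classes + 1))
        self.mixing = np.asarray(self.mixing, dtype=float)
        if len(self.mixing) != self.n_classes + 1:
            raise ValueError("mixing needs K+1 entries (non-HBD last)")
        if abs(self.mixing.sum() - 1.0) > 1e-8:
            raise ValueError("mixing coefficients must sum to 1")
        if not (0 < self.error_rate < 0.5):
            raise ValueError("error_rate must lie in (0, 0.5)")

    @property
    def state_rates(self) -> np.ndarray:
        """Per-state rates, non-HBD class sharing the last HBD rate."""
        return np.concatenate([self.rates, self.rates[-1:]])


def _emission_table(freq_b: np.ndarray, eps: float) -> np.ndarray:
    """(2, n_snp, 3) observed-genotype probabilities for (HBD, non-HBD).

    A true genotype is observed intact with probability 1-eps, otherwise one
    of the other two codes uniformly.
    """
    p = np.asarray(freq_b, dtype=float)
    q = 1.0 - p
    true_hbd = np.stack([q, np.zeros_like(p), p], axis=1)
    true_non = np.stack([q * q, 2 * p * q, p * p], axis=1)
    tab = np.stack([true_hbd, true_non])
    return tab * (1.0 - 1.5 * eps) + 0.5 * eps


def emission_logprob(genotype_code: int, allele_freq: float, state: str,
                     error_rate: float = 1e-3) -> float:
    """Log emission probability of one genotype code (0/1/2 copies of
    allele B) under ``state`` in {"hbd", "non_hbd"}."""
    if not (0 < allele_freq < 1):
        raise ValueError("allele_freq must lie strictly inside (0, 1); "
                         "monomorphic SNPs must be pre-filtered")
    tab = _emission_table(np.array([allele_freq]), error_rate)
    row = {"hbd": 0, "non_hbd": 1}[state]
    p = tab[row, 0, genotype_code]
    return float(np.log(p)) if p > 0 else -np.inf


def transition_matrix(distance_morgans: float, model: HbdModel) -> np.ndarray:
    """(K+1) x (K+1) state-transition matrix over a map distance.

    T = diag(stay) + (1 - stay) outer mixing, stay_c = exp(-R_c d).
    """
    if distance_morgans < 0:
        raise ValueError("distance must be >= 0")
    stay = np.exp(-model.state_rates * distance_morgans)
    return np.diag(stay) + (1.0 - stay)[:, None] * model.mixing[None, :]


@dataclass
class HbdDecoding:
    f_hbd: pd.Series
    hbd_posterior: np.ndarray  # animals x SNPs, total HBD probability
    loglik: np.ndarray  # per animal
    mixing: np.ndarray  # per animal x (K+1), final EM estimates
    n_iter: int
    class_posteriors: np.ndarray | None = None  # animals x SNPs x (K+1)


def decode(geno: GenotypeMatrix, model: HbdModel | None = None,
           morgan_per_bp: float = MORGAN_PER_BP_DEFAULT,
           estimate_mixing: bool = True, max_iter: int = 100,
           tol: float = 1e-6,
           store_class_posteriors: bool = False) -> HbdDecoding:
    """Forward-backward HBD decoding for every animal.

    Genotypes must be complete and MAF-filtered (monomorphic SNPs break the
    HBD emissions).  Allele frequencies default to sample frequencies.
    Chromosomes are decoded independently; the chain restarts from the
    mixing distribution at each chromosome start.
    """
    if geno.has_missing():
        raise ValueError("decode requires complete genotypes")
    K = model.n_classes if model else 10
    model = model or HbdModel()
    freq = (model.allele_freqs if model.allele_freqs is not None
            else geno.codes.mean(axis=0) / 2.0)
    if ((freq <= 0) | (freq >= 1)).any():
        j = int(np.argmax((freq <= 0) | (freq >= 1)))
        raise ValueError(f"monomorphic SNP at index {j}; apply the MAF filter")
    S = K + 1
    n_anim, n_snp = geno.codes.shape
    emis = _emission_table(freq, model.error_rate)  # (2, n_snp, 3)
    # per-animal, per-locus emissions for (HBD-class, non-HBD) states
    codes = geno.codes.astype(np.intp)
    cols = np.arange(n_snp)
    e_hbd = emis[0][cols, codes]   # (n_anim, n_snp)
    e_non = emis[1][cols, codes]
    rates = model.state_rates
    slices = _chrom_slices(geno.snp_map)
    pos = geno.snp_map["pos_bp"].to_numpy()

    P = np.tile(model.mixing, (n_anim, 1))  # per-animal mixing
    it = 0
    prev_ll = None
    while True:
        ll = np.zeros(n_anim)
        entries = np.zeros((n_anim, S))
        hbd_post = np.empty((n_anim, n_snp))
        full_post = (np.empty((n_anim, n_snp, S))
                     if store_class_posteriors else None)
        for _, a, b in slices:
            ll_c, ent_c = _decode_chrom(
                e_hbd[:, a:b], e_non[:, a:b],
                np.diff(pos[a:b]) * morgan_per_bp, rates, P, K,
                hbd_post[:, a:b],
                None if full_post is None else full_post[:, a:b, :])
            ll += ll_c
            entries += ent_c
        it += 1
        if not estimate_mixing:
            break
        newP = entries / entries.sum(axis=1, keepdims=True)
        done = (prev_ll is not None
                and np.max(np.abs(ll - prev_ll)) < tol) or it >= max_iter
        prev_ll = ll
        P = newP
        if done:
            break
    f_hbd = pd.Series(hbd_post.mean(axis=1), index=geno.samples,
                      name="F_HBD")
    return HbdDecoding(f_hbd, hbd_post, ll, P, it,
                       class_posteriors=full_post)


def _decode_chrom(e_hbd, e_non, d_morgans, rates, P, K, hbd_out, full_out):
    """Scaled forward-backward on one chromosome for all animals at once.

    The transition matrix is diagonal-plus-rank-one, so each step is O(S)
    per animal.  Returns (loglik per animal, expected segment entries per
    state per animal) and fills the posterior output arrays.
    """
    n_anim, T = e_hbd.shape
    S = K + 1
    B = np.empty((n_anim, S))
    stay = np.exp(-np.outer(d_morgans, rates))  # (T-1, S)

    def bmat(t):
        B[:, :K] = e_hbd[:, t][:, None]
        B[:, K] = e_non[:, t]
        return B

    alphas = np.empty((T, n_anim, S))
    c = np.empty((T, n_anim))
    a = P * bmat(0)
    c[0] = a.sum(axis=1)
    a /= c[0][:, None]
    alphas[0] = a
    for t in range(1, T):
        s = stay[t - 1]
        leave = a @ (1.0 - s)
        pred = a * s + leave[:, None] * P
        a = pred * bmat(t)
        c[t] = a.sum(axis=1)
        a = a / c[t][:, None]
        alphas[t] = a

    entries = np.zeros((n_anim, S))
    beta = np.ones((n_anim, S))
    g = alphas[T - 1] * beta
    _store(g, T - 1, K, hbd_out, full_out)
    for t in range(T - 1, 0, -1):
        bb = bmat(t) * beta / c[t][:, None]
        s = stay[t - 1]
        leave_prev = alphas[t - 1] @ (1.0 - s)  # (n_anim,)
        entries += leave_prev[:, None] * P * bb
        beta = s * bb + (1.0 - s) * (P * bb).sum(axis=1)[:, None]
        g = alphas[t - 1] * beta
        g = g / g.sum(axis=1, keepdims=True)
        _store(g, t - 1, K, hbd_out, full_out)
    g0 = alphas[0] * beta
    g0 = g0 / g0.sum(axis=1, keepdims=True)
    entries += g0  # the chain's first segment is also drawn from the mixing
    ll = np.log(c).sum(axis=0)
    return ll, entries


def _store(gamma, t, K, hbd_out, full_out):
    hbd_out[:, t] = gamma[:, :K].sum(axis=1)
    if full_out is not None:
        full_out[:, t, :] = gamma
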