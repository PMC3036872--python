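"""Haplotype diversity, nucleotide diversity and pairwise genetic distances.

Haplotype (gene) diversity follows Nei (1987):

    h = n (1 - sum_i p_i^2) / (n - 1)

with sampling variance

    V(h) = 2/(n(n-1)) [ 2(n-2)(sum p^3 - (sum p^2)^2) + sum p^2 - (sum p^2)^2 ].

Nucleotide diversity is the mean per-site proportion of differences over all
sequence pairs (p-distance on pairwise-complete sites by default); its total
variance includes both the sampling and the stochastic (coalescent) term:

    V(pi) = (n+1)/(3(n-1)L) pi + 2(n^2+n+3)/(9n(n-1)) pi^2.

Model-corrected distances use the Tamura-Nei (1993) closed form, optionally
with gamma rate heterogeneity; these are used for the AMOVA/Phi_ST analyses
while pi itself is reported on uncorrected proportions.  The invariant-sites
fraction is carried for reporting only and does not rescale distances (there
is no standard closed form; the reference implementations ignore it too).

Sites containing a gap or N in either member of a pair are excluded from that
pair's comparison (pairwise deletion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .alignio import Alignment

__all__ = [
    "DistanceModelParams",
    "DiversityEstimates",
    "pairwise_differences",
    "haplotype_diversity",
    "nucleotide_diversity",
    "tn93_distance",
    "distance_matrix",
    "empirical_base_frequencies",
    "SaturationError",
]


class SaturationError(ValueError):
    """A TN93 logarithm/power argument became non-positive (saturated pair)."""


@dataclass
class DistanceModelParams:
    """Substitution-model settings for pairwise distances.

    model: one of ``p-distance``, ``TN93``, ``TN93+G``.
    alpha: gamma shape for ``TN93+G`` (the control-region estimate is 0.61).
    invariant_fraction: reported but not used in the correction.
    freqs: base frequencies (A, C, G, T); ``None`` means empirical.
    """

    model: str = "p-distance"
    alpha: float = 0.61
    invariant_fraction: float = 0.0
    freqs: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.model not in ("p-distance", "TN93", "TN93+G"):
            raise ValueError(f"unknown distance model {self.model!r}")
        if self.alpha <= 0:
            raise ValueError("gamma shape must be > 0")
        if not (0 <= self.invariant_fraction < 1):
            raise ValueError("invariant fraction must be in [0, 1)")


@dataclass
class DiversityEstimates:
    h: float
    sd_h: float
    pi: float
    sd_pi: float
    n: int
    K: int


def _char_matrix(aln: Alignment) -> tuple[np.ndarray, np.ndarray]:
    arr = aln.to_array()
    valid = (arr != "-") & (arr != "N")
    return arr, valid


def pairwise_differences(aln: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise difference counts and numbers of comparable sites.

    Returns ``(diffs, comparable)``: symmetric integer matrices where entry
    (i, j) counts sites at which both sequences carry an unambiguous base and
    the bases differ, and the number of such jointly unambiguous sites.
    """
    arr, valid = _char_matrix(aln)
    n = aln.n
    diffs = np.zeros((n, n), dtype=int)
    comp = np.zeros((n, n), dtype=int)
    for i in range(n):
        both = valid[i] & valid
        diffs[i] = ((arr[i] != arr) & both).sum(axis=1)
        comp[i] = both.sum(axis=1)
    np.fill_diagonal(diffs, 0)
    return diffs, comp


def haplotype_diversity(counts, n: int | None = None) -> tuple[float, float]:
    """Nei's haplotype diversity and its standard deviation from counts."""
    counts = np.asarray(list(counts), dtype=float)
    if (counts < 1).any():
        raise ValueError("haplotype counts must be >= 1")
    total = counts.sum()
    if n is None:
        n = int(total)
    if n != total:
        raise ValueError(f"counts sum to {total}, not n={n}")
    if n < 2:
        raise ValueError("haplotype diversity undefined for n < 2")
    p = counts / n
    sum2 = (p**2).sum()
    sum3 = (p**3).sum()
    h = n * (1.0 - sum2) / (n - 1)
    var = (2.0 / (n * (n - 1))) * (2.0 * (n - 2) * (sum3 - sum2**2) + sum2 - sum2**2)
    return float(h), float(np.sqrt(max(var, 0.0)))


def nucleotide_diversity(
    aln: Alignment, model: DistanceModelParams | None = None
) -> tuple[float, float]:
    """Mean per-site pairwise diversity and its total standard deviation."""
    if aln.n < 2:
        raise ValueError("nucleotide diversity needs n >= 2")
    n = aln.n
    if model is not None and model.model != "p-distance":
        d = distance_matrix(aln, model)
        iu = np.triu_indices(n, k=1)
        per_site = d[iu]
        _, comp = pairwise_differences(aln)
        L_eff = float(comp[iu].mean())
    else:
        diffs, comp = pairwise_differences(aln)
        iu = np.triu_indices(n, k=1)
        usable = comp[iu] > 0
        if not usable.all():
            warnings.warn("pairs with zero comparable sites excluded from pi")
        per_site = diffs[iu][usable] / comp[iu][usable]
        L_eff = float(comp[iu][usable].mean())
    pi = float(per_site.mean())
    var = (n + 1) / (3.0 * (n - 1) * L_eff) * pi + 2.0 * (n * n + n + 3) / (
        9.0 * n * (n - 1)
    ) * pi**2
    return pi, float(np.sqrt(max(var, 0.0)))


def empirical_base_frequencies(aln: Alignment) -> tuple[float, float, float, float]:
    arr, valid = _char_matrix(aln)
    chars = arr[valid]
    total = chars.size
    return tuple(float((chars == b).sum()) / total for b in "ACGT")  # type: ignore[return-value]


def _tn93_from_proportions(
    P1: float, P2: float, Q: float, freqs, alpha: float | None
) -> float:
    gA, gC, gG, gT = freqs
    if min(freqs) <= 0:
        raise ValueError("TN93 requires strictly positive base frequencies")
    gR, gY = gA + gG, gC + gT
    k1 = 2.0 * gA * gG / gR
    k2 = 2.0 * gT * gC / gY
    k3 = 2.0 * (gR * gY - gA * gG * gY / gR - gT * gC * gR / gY)
    w1 = 1.0 - P1 * gR / (2.0 * gA * gG) - Q / (2.0 * gR)
    w2 = 1.0 - P2 * gY / (2.0 * gT * gC) - Q / (2.0 * gY)
    w3 = 1.0 - Q / (2.0 * gR * gY)
    if min(w1, w2, w3) <= 0:
        raise SaturationError("saturated pair: TN93 correction undefined")
    if alpha is None:
        d = -k1 * np.log(w1) - k2 * np.log(w2) - k3 * np.log(w3)
    else:
        a = float(alpha)
        d = (
            k1 * a * (w1 ** (-1.0 / a) - 1.0)
            + k2 * a * (w2 ** (-1.0 / a) - 1.0)
            + k3 * a * (w3 ** (-1.0 / a) - 1.0)
        )
    return float(max(d, 0.0))


def tn93_distance(seq_i: str, seq_j: str, params: DistanceModelParams) -> float:
    """Tamura-Nei (1993) distance between two aligned sequences.

    Uses the closed form on pairwise-complete sites; ``TN93+G`` applies the
    gamma-rates correction with shape ``params.alpha``.
    """
    a = np.array(list(seq_i.upper()))
    b = np.array(list(seq_j.upper()))
    if a.shape != b.shape:
        raise ValueError("sequences differ in length")
    ok = np.isin(a, list("ACGT")) & np.isin(b, list("ACGT"))
    if not ok.any():
        raise ValueError("no pairwise-complete sites")
    a, b = a[ok], b[ok]
    L = a.size
    diff = a != b
    pairset = [frozenset(x) for x in zip(a[diff], b[diff])]
    P1 = sum(1 for s in pairset if s == frozenset("AG")) / L
    P2 = sum(1 for s in pairset if s == frozenset("CT")) / L
    Q = (diff.sum() / L) - P1 - P2
    if params.freqs is not None:
        freqs = params.freqs
    else:
        chars = np.concatenate([a, b])
        freqs = tuple(float((chars == x).sum()) / chars.size for x in "ACGT")
    alpha = params.alpha if params.model == "TN93+G" else None
    if params.model == "p-distance":
        return float(diff.sum() / L)
    return _tn93_from_proportions(P1, P2, Q, freqs, alpha)


def distance_matrix(aln: Alignment, params: DistanceModelParams) -> np.ndarray:
    """Symmetric matrix of pairwise distances under ``params``.

    For the model-based distances the base frequencies default to the
    empirical frequencies of the whole alignment (not of each pair), which
    keeps the matrix internally consistent.
    """
    n = aln.n
    d = np.zeros((n, n))
    if params.model == "p-distance":
        diffs, comp = pairwise_differences(aln)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(comp > 0, diffs / np.maximum(comp, 1), 0.0)
        np.fill_diagonal(d, 0.0)
        return d
    use = params
    if params.freqs is None:
        use = DistanceModelParams(
            params.model, params.alpha, params.invariant_fraction, empirical_base_frequencies(aln)
        )
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d[i, j] = d[j, i] = tn93_distance(aln.seqs[i], aln.seqs[j], use)
            except SaturationError as exc:
                raise SaturationError(f"{exc} (pair {aln.ids[i]}, {aln.ids[j]})") from None
    return d
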