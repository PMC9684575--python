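"""96-channel mutation catalogs and maximum-likelihood signature fitting.

Single-base substitutions are binned by pyrimidine-strand substitution class
(C>A, C>G, C>T, T>A, T>C, T>G) and 5'/3' flanking base, giving the standard
96 trinucleotide channels. Signature exposures are estimated by maximising
the multinomial log-likelihood

    L(w) = sum_c x_c * log(sum_k w_k * S_kc)

over the probability simplex with an expectation-maximization update; the
likelihood is non-decreasing at every step and the iteration is
deterministic (uniform initialisation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import Variant, revcomp

logger = logging.getLogger(__name__)

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"
CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}" for sub in SUBSTITUTIONS for five in _BASES for three in _BASES
)
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}


@dataclass
class MutationCatalog96:
    """Counts over the 96 canonical trinucleotide channels."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError("catalog must have exactly 96 channels")
        if (self.counts < 0).any():
            raise ValueError("catalog counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "MutationCatalog96":
        counts = np.zeros(96)
        for channel, n in mapping.items():
            counts[_CHANNEL_INDEX[channel]] = n
        return cls(counts)

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CHANNELS), name="count")


@dataclass
class SignatureMatrix:
    """K named signatures, each a probability vector over the 96 channels."""

    names: list[str]
    matrix: np.ndarray  # shape (K, 96), rows sum to 1

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape != (len(self.names), 96):
            raise ValueError("signature matrix must be (K, 96) with K names")
        if (self.matrix < 0).any():
            raise ValueError("signature probabilities must be non-negative")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("each signature must sum to 1 within 1e-6")

    @property
    def k(self) -> int:
        return len(self.names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix.T, index=list(CHANNELS), columns=self.names)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SignatureMatrix":
        df = df.reindex(list(CHANNELS))
        if df.isna().any().any():
            raise ValueError("signature table is missing channels")
        return cls(names=list(df.columns), matrix=df.to_numpy().T)


@dataclass(frozen=True)
class SignatureFit:
    names: tuple[str, ...]
    weights: np.ndarray
    log_likelihood: float
    n_mutations: int
    n_iter: int

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("weights must be non-negative and sum to 1 within 1e-8")
        object.__setattr__(self, "weights", w)

    def weight_of(self, name: str) -> float:
        if name not in self.names:
            raise KeyError(f"unknown signature {name!r}")
        return float(self.weights[self.names.index(name)])


def snv_channel(ref: str, alt: str, five: str, three: str) -> str:
    """Canonical channel of a substitution given its flanking bases; purine
    references are folded onto the pyrimidine strand."""
    ref, alt, five, three = ref.upper(), alt.upper(), five.upper(), three.upper()
    if ref in "AG":
        ref, alt = revcomp(ref), revcomp(alt)
        five, three = revcomp(three), revcomp(five)
    return f"{five}[{ref}>{alt}]{three}"


def build_catalog(snvs: Sequence[Variant], reference: Mapping[str, str]) -> MutationCatalog96:
    """Bin single-base substitutions into the 96-channel catalog.

    ``reference`` maps contig name to sequence. Variants whose flanking base
    falls off the contig are skipped and logged; total counts otherwise equal
    the number of input SNVs.
    """
    counts = np.zeros(96)
    for v in snvs:
        if len(v.ref) != 1 or len(v.alt) != 1:
            raise ValueError(f"{v.variant_id}: not a single-base substitution")
        seq = reference[v.contig]
        if v.pos < 2 or v.pos > len(seq) - 1:
            logger.warning("variant %s at contig edge; skipped from catalog", v.variant_id)
            continue
        five, three = seq[v.pos - 2], seq[v.pos]
        counts[_CHANNEL_INDEX[snv_channel(v.ref, v.alt, five, three)]] += 1
    return MutationCatalog96(counts)


def fit_signature_weights(
    catalog: MutationCatalog96,
    sigs: SignatureMatrix,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    return_trace: bool = False,
):
    """Maximum-likelihood signature exposures by EM.

    Update: w_k <- w_k * sum_c x_c S_kc / (sum_j w_j S_jc) / N. Stops when
    the log-likelihood gain drops below ``tol``. Raises on an empty catalog
    or when an observed channel has zero mass under every signature (the
    likelihood would be -inf for all weights).
    """
    x = catalog.counts
    n = x.sum()
    if n <= 0:
        raise ValueError("cannot fit signatures to an empty catalog")
    S = sigs.matrix  # (K, 96)
    observed = x > 0
    if (S[:, observed].sum(axis=0) == 0).any():
        raise ValueError("an observed channel has zero probability under every signature")

    k = sigs.k
    w = np.full(k, 1.0 / k)
    prev_ll = -np.inf
    trace: list[float] = []
    for it in range(1, max_iter + 1):
        mix = w @ S  # (96,)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = float(np.sum(x[observed] * np.log(mix[observed])))
        if ll < prev_ll - 1e-9:
            raise AssertionError("EM log-likelihood decreased")  # pragma: no cover
        trace.append(ll)
        if ll - prev_ll < tol and it > 1:
            prev_ll = ll
            break
        prev_ll = ll
        resp = (w[:, None] * S) / np.where(mix > 0, mix, 1.0)  # (K, 96)
        w = (resp * x).sum(axis=1) / n
        w = np.clip(w, 0.0, None)
        w /= w.sum()
    fit = SignatureFit(
        names=tuple(sigs.names),
        weights=w,
        log_likelihood=prev_ll,
        n_mutations=int(n),
        n_iter=it,
    )
    return (fit, trace) if return_trace else fit


def signature_fraction(fit: SignatureFit, name: str) -> float:
    """The fitted exposure of one named signature."""
    return fit.weight_of(name)
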