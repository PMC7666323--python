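"""Mutational-signature extraction over the 96 trinucleotide contexts.

Every single-nucleotide variant with a known flanking context is placed in
one of 96 substitution categories (pyrimidine-strand convention). Counts are
pooled per cohort (or kept per sample) into a spectrum matrix V, which is
factorized as V ~ W H by non-negative matrix factorization under the
Frobenius objective with multiplicative updates: H's rows are the signatures
(renormalized to probability profiles over the 96 categories) and W carries
the per-row exposures. Extracted signatures are matched to a reference
catalog by cosine similarity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .contexts import CONTEXT_LABELS, SUBSTITUTIONS, context_label
from .io import MutationRecord

logger = logging.getLogger(__name__)

__all__ = [
    "classify_context",
    "Spectrum",
    "build_spectrum",
    "nmf",
    "extract_signatures",
    "SignatureModel",
    "SignatureResults",
    "match_catalog",
    "cosine_similarity",
    "scan_ranks",
    "pick_rank_elbow",
    "synthetic_catalog",
    "plot_spectrum",
]


def classify_context(record: MutationRecord) -> str | None:
    """96-category label for an SNV record, or ``None`` if unclassifiable.

    Indels, records without a stored context, and records whose context
    middle base disagrees with the reference allele (warned, not fatal) are
    unclassifiable.
    """
    if not record.is_snv or record.context3 is None:
        return None
    label = context_label(record.ref, record.alt, record.context3)
    if label is None and len(record.context3) == 3 and record.context3[1] != record.ref:
        logger.warning(
            "context %r middle base disagrees with ref %r at %s:%d; "
            "record left unclassified",
            record.context3,
            record.ref,
            record.chrom,
            record.pos,
        )
    return label


@dataclass
class Spectrum:
    """Rows x 96 category counts plus the per-row unclassifiable tally."""

    counts: pd.DataFrame
    unclassified: pd.Series

    @property
    def row_ids(self) -> list[str]:
        return list(self.counts.index)


def build_spectrum(
    muts: Iterable[MutationRecord],
    cohort: Iterable[str],
    granularity: str = "per_cohort",
    row_id: str = "cohort",
) -> Spectrum:
    """Tally classifiable SNVs of a cohort into the 96-category matrix.

    ``granularity='per_cohort'`` pools all samples into a single row named
    ``row_id``; ``'per_sample'`` yields one row per cohort sample (all-zero
    rows included for samples without classifiable SNVs).
    """
    if granularity not in ("per_cohort", "per_sample"):
        raise ValueError(f"unknown granularity {granularity!r}")
    cohort = sorted(set(cohort))
    cohort_set = set(cohort)
    rows = [row_id] if granularity == "per_cohort" else cohort
    counts = pd.DataFrame(
        0, index=pd.Index(rows, name="row"), columns=list(CONTEXT_LABELS), dtype=int
    )
    unclassified = pd.Series(0, index=counts.index, dtype=int)
    for rec in muts:
        if rec.sample_id not in cohort_set:
            continue
        key = row_id if granularity == "per_cohort" else rec.sample_id
        label = classify_context(rec)
        if label is None:
            unclassified[key] += 1
        else:
            counts.loc[key, label] += 1
    return Spectrum(counts=counts, unclassified=unclassified)


# ---------------------------------------------------------------------------
# NMF


def _mu_nmf(
    v: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """One multiplicative-update run; returns W, H and the error trace."""
    eps = 1e-12
    n, m = v.shape
    scale = math.sqrt(max(v.mean(), eps) / k)
    w = rng.uniform(0.0, 1.0, size=(n, k)) * scale + eps
    h = rng.uniform(0.0, 1.0, size=(k, m)) * scale + eps
    trace: list[float] = [float(np.linalg.norm(v - w @ h))]
    for _ in range(max_iter):
        h *= (w.T @ v) / (w.T @ w @ h + eps)
        w *= (v @ h.T) / (w @ (h @ h.T) + eps)
        err = float(np.linalg.norm(v - w @ h))
        prev = trace[-1]
        trace.append(err)
        if prev - err <= tol * max(trace[0], eps):
            break
    return w, h, trace


def nmf(
    v: np.ndarray,
    k: int,
    n_starts: int = 10,
    seed: int = 17,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    """Best-of-``n_starts`` multiplicative-update NMF of ``v`` (rows x 96).

    Returns ``(W, H, reconstruction_error, error_trace)`` for the start with
    the lowest final Frobenius error. Deterministic given ``seed``.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 2:
        raise ValueError("spectrum must be a 2-D array")
    if np.any(v < 0):
        raise ValueError("spectrum entries must be non-negative")
    if v.sum() <= 0:
        raise ValueError("spectrum must contain at least one positive entry")
    if not 1 <= k <= min(v.shape):
        raise ValueError(f"rank k={k} must lie in [1, min(rows, cols)={min(v.shape)}]")
    seeds = np.random.SeedSequence(seed).spawn(n_starts)
    best: tuple[np.ndarray, np.ndarray, list[float]] | None = None
    for ss in seeds:
        w, h, trace = _mu_nmf(v, k, np.random.default_rng(ss), max_iter, tol)
        if best is None or trace[-1] < best[2][-1]:
            best = (w, h, trace)
    w, h, trace = best
    return w, h, trace[-1], trace


def extract_signatures(
    spectrum: Spectrum | pd.DataFrame,
    k: int,
    n_starts: int = 10,
    seed: int = 17,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> "SignatureResults":
    """Functional wrapper around :class:`SignatureModel`."""
    return SignatureModel(spectrum, k).fit(
        n_starts=n_starts, seed=seed, max_iter=max_iter, tol=tol
    )


class SignatureModel:
    """NMF signature model for a spectrum matrix at a fixed rank ``k``."""

    def __init__(self, spectrum: Spectrum | pd.DataFrame, k: int) -> None:
        counts = spectrum.counts if isinstance(spectrum, Spectrum) else spectrum
        if list(counts.columns) != list(CONTEXT_LABELS):
            raise ValueError("spectrum columns must be the 96 canonical context labels")
        self.counts = counts
        self.k = int(k)

    def fit(
        self,
        n_starts: int = 10,
        seed: int = 17,
        max_iter: int = 2000,
        tol: float = 1e-6,
    ) -> "SignatureResults":
        w, h, err, trace = nmf(
            self.counts.to_numpy(dtype=float),
            self.k,
            n_starts=n_starts,
            seed=seed,
            max_iter=max_iter,
            tol=tol,
        )
        # fold the signature scale into the exposures so each signature is a
        # probability profile over the 96 categories
        col_sums = h.sum(axis=1)
        col_sums[col_sums == 0] = 1.0
        signatures = (h / col_sums[:, None]).T  # 96 x k
        exposures = w * col_sums[None, :]  # rows x k
        sig_names = [f"S{i + 1}" for i in range(self.k)]
        return SignatureResults(
            signatures=pd.DataFrame(
                signatures, index=list(CONTEXT_LABELS), columns=sig_names
            ),
            exposures=pd.DataFrame(
                exposures, index=self.counts.index, columns=sig_names
            ),
            reconstruction_error=err,
            error_trace=trace,
        )


@dataclass
class SignatureResults:
    """Extracted signature profiles (96 x k, columns sum to 1) and exposures."""

    signatures: pd.DataFrame
    exposures: pd.DataFrame
    reconstruction_error: float
    error_trace: list[float]

    @property
    def k(self) -> int:
        return self.signatures.shape[1]

    def match(self, catalog: pd.DataFrame, threshold: float = 0.75) -> pd.DataFrame:
        return match_catalog(self.signatures, catalog, threshold=threshold)

    def summary(self) -> str:
        lines = [
            "NMF mutational signatures",
            "=" * 48,
            f"rank k:               {self.k}",
            f"spectrum rows:        {self.exposures.shape[0]}",
            f"reconstruction error: {self.reconstruction_error:.6g} (Frobenius)",
            f"iterations:           {len(self.error_trace) - 1}",
            "-" * 48,
            "exposures:",
            self.exposures.to_string(float_format=lambda v: f"{v:.1f}"),
        ]
        return "\n".join(lines)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def match_catalog(
    signatures: pd.DataFrame, catalog: pd.DataFrame, threshold: float = 0.75
) -> pd.DataFrame:
    """Assign each extracted signature its argmax-cosine catalog entry.

    Assignments with cosine below ``threshold`` are labelled ``unassigned``.
    Returns a frame with columns ``extracted``, ``catalog_name``, ``cosine``.
    """
    catalog = catalog.loc[list(CONTEXT_LABELS)]
    sigs = signatures.loc[list(CONTEXT_LABELS)]
    rows = []
    cat_mat = catalog.to_numpy(dtype=float)
    cat_norms = np.linalg.norm(cat_mat, axis=0)
    for name in sigs.columns:
        u = sigs[name].to_numpy(dtype=float)
        nu = np.linalg.norm(u)
        if nu == 0:
            rows.append({"extracted": name, "catalog_name": "unassigned", "cosine": 0.0})
            continue
        cos = (cat_mat.T @ u) / (cat_norms * nu)
        j = int(np.argmax(cos))
        best = float(cos[j])
        rows.append(
            {
                "extracted": name,
                "catalog_name": catalog.columns[j] if best >= threshold else "unassigned",
                "cosine": best,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rank selection


def scan_ranks(
    spectrum: Spectrum | pd.DataFrame,
    ks: Sequence[int] = range(2, 7),
    n_starts: int = 10,
    seed: int = 17,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Reconstruction error and explained variance for each candidate rank."""
    counts = spectrum.counts if isinstance(spectrum, Spectrum) else spectrum
    v = counts.to_numpy(dtype=float)
    total = float(np.linalg.norm(v))
    rows = []
    for k in ks:
        _, _, err, _ = nmf(v, k, n_starts=n_starts, seed=seed, max_iter=max_iter, tol=tol)
        rows.append(
            {
                "k": k,
                "reconstruction_error": err,
                "explained_variance": 1.0 - (err / total) ** 2 if total > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def pick_rank_elbow(scan: pd.DataFrame) -> int:
    """Elbow of the error curve: the rank with maximal discrete curvature.

    With errors e(k) over consecutive ranks, returns the interior k
    maximizing (e(k-1) - e(k)) - (e(k) - e(k+1)); for fewer than three
    ranks, the smallest rank within 1% of the best error is returned.
    """
    scan = scan.sort_values("k").reset_index(drop=True)
    e = scan["reconstruction_error"].to_numpy(dtype=float)
    ks = scan["k"].to_numpy(dtype=int)
    if len(ks) < 3:
        best = e.min()
        return int(ks[np.argmax(e <= best * 1.01)])
    curvature = (e[:-2] - e[1:-1]) - (e[1:-1] - e[2:])
    return int(ks[1:-1][np.argmax(curvature)])


# ---------------------------------------------------------------------------
# synthetic catalog


def synthetic_catalog(
    n_signatures: int = 30, seed: int = 7, concentration: float = 0.1
) -> pd.DataFrame:
    """A synthetic stand-in reference catalog of 96-context profiles.

    These are *not* measured COSMIC profiles: each column is a sparse random
    probability profile (Dirichlet with a small concentration, so profiles are
    peaked and mutually near-orthogonal), deterministically generated from
    ``seed`` and named ``"Signature 1" ... "Signature N"`` so that code paths
    expecting a COSMIC-v2-shaped catalog (96 rows x 30 named columns) can be
    exercised without the external database.
    """
    rng = np.random.default_rng(seed)
    profiles = rng.dirichlet([concentration] * len(CONTEXT_LABELS), size=n_signatures).T
    return pd.DataFrame(
        profiles,
        index=list(CONTEXT_LABELS),
        columns=[f"Signature {i + 1}" for i in range(n_signatures)],
    )


# ---------------------------------------------------------------------------
# plotting

_CLASS_COLORS = {
    "C>A": "#03bcee",
    "C>G": "#010101",
    "C>T": "#e32926",
    "T>A": "#cac9c9",
    "T>C": "#a1cf63",
    "T>G": "#edc8c5",
}


def plot_spectrum(row: pd.Series, ax=None, title: str | None = None):
    """Bar chart of one 96-category spectrum row, colored by substitution class."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(12, 3))
    values = row.reindex(list(CONTEXT_LABELS)).to_numpy(dtype=float)
    colors = [
        _CLASS_COLORS[f"{r}>{a}"] for r, a in SUBSTITUTIONS for _ in range(16)
    ]
    ax.bar(range(96), values, color=colors, width=0.8)
    ax.set_xticks(range(0, 96, 16))
    ax.set_xticklabels([f"{r}>{a}" for r, a in SUBSTITUTIONS])
    ax.set_ylabel("mutations")
    if title:
        ax.set_title(title)
    return ax
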