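"""Significantly-mutated-gene detection against a length-normalized background.

The model: pooled over a cohort, M protein-altering mutations fall on a gene
set with total coding length L_tot, giving a single background rate
r = M / L_tot per bp. For a gene of length L_g the expected count is
e_g = r * L_g, and genes with more observed mutations than expected are
tested one-sided (right tail) for an elevated per-bp rate:

* ``conditional_exact`` (default) — the exact conditional rate-ratio test:
  given M total events, the gene's share is Binomial(M, L_g / L_tot) under the
  null, so p = P(Bin(M, L_g/L_tot) >= x_g). This is the conditional test behind
  two-sample exact rate-ratio procedures.
* ``poisson_tail`` — the plain Poisson tail p = P(Poisson(e_g) >= x_g).

Multiple testing is adjusted with Storey q-values; genes are called
significant at p < 0.01 and q < 0.25 by default. Subtype-preferential genes
are then extracted by the fold criterion: significant in the target cohort
with a counterpart p-value at least ``fold`` times larger.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io import MutationRecord, count_nonsynonymous

__all__ = [
    "BackgroundModel",
    "background_rate",
    "gene_rate_test",
    "estimate_pi0",
    "storey_qvalues",
    "call_smgs",
    "differential_extract",
    "SmgModel",
    "SmgResults",
]

PVALUE_FLOOR = 1e-300


@dataclass(frozen=True)
class BackgroundModel:
    """Global per-bp background mutation rate: M events over L_tot coding bp."""

    total_mutations: int
    total_length_bp: int

    def __post_init__(self) -> None:
        if self.total_mutations < 0:
            raise ValueError("total mutation count must be non-negative")
        if self.total_length_bp <= 0:
            raise ValueError("total gene length must be positive")

    @property
    def rate_per_bp(self) -> float:
        return self.total_mutations / self.total_length_bp

    def expected(self, gene_length_bp: int) -> float:
        return self.rate_per_bp * gene_length_bp


def background_rate(
    counts: Mapping[str, int], lengths: Mapping[str, int]
) -> BackgroundModel:
    """Pool observed counts over the whole length table into a background rate.

    The denominator sums the lengths of *all* genes in the length table,
    including genes with zero observed mutations; every counted gene must
    have a length entry.
    """
    missing = sorted(g for g in counts if g not in lengths)
    if missing:
        raise ValueError(
            f"{len(missing)} counted genes have no length entry: {missing[:10]}"
        )
    total = int(sum(counts.values()))
    l_tot = int(sum(lengths.values()))
    return BackgroundModel(total_mutations=total, total_length_bp=l_tot)


def gene_rate_test(
    x_g: int,
    length_bp: int,
    background: BackgroundModel,
    method: str = "conditional_exact",
) -> float:
    """Right-tailed p-value for an elevated per-bp mutation rate in one gene."""
    if x_g < 0:
        raise ValueError("observed count must be non-negative")
    if length_bp <= 0:
        raise ValueError("gene length must be positive")
    if length_bp >= background.total_length_bp:
        raise ValueError("gene length must be smaller than the total length")
    if x_g > background.total_mutations:
        raise ValueError("observed count exceeds the total mutation count")
    if method == "conditional_exact":
        pi0 = length_bp / background.total_length_bp
        p = stats.binom.sf(x_g - 1, background.total_mutations, pi0)
    elif method == "poisson_tail":
        p = stats.poisson.sf(x_g - 1, background.expected(length_bp))
    else:
        raise ValueError(f"unknown test method {method!r}")
    return float(min(max(p, 0.0), 1.0)) if x_g > 0 else 1.0


# ---------------------------------------------------------------------------
# Storey q-values

_DEFAULT_LAMBDAS = np.arange(0.05, 0.96, 0.05)


def estimate_pi0(p_values: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Estimate the null proportion pi0 from the p-value histogram.

    For m >= 100 p-values, pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is
    evaluated on the lambda grid and smoothed with a cubic fit evaluated at
    max(lambda); for smaller m the single-point plug-in at lambda = 0.5 is
    used. The estimate is capped into [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if lambdas is None:
        lambdas = _DEFAULT_LAMBDAS
    m = p.size
    if m < 100:
        pi0 = np.mean(p > 0.5) / 0.5
    else:
        pi0_lam = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambdas])
        # pi0(lambda) has variance ~ lambda / (m (1 - lambda)) under the null;
        # weight the cubic fit by the inverse standard deviation so the noisy
        # high-lambda points do not dominate the endpoint evaluation
        weights = np.sqrt((1.0 - lambdas) / lambdas)
        coeffs = np.polyfit(lambdas, pi0_lam, deg=3, w=weights)
        pi0 = float(np.polyval(coeffs, lambdas.max()))
    return float(min(max(pi0, 0.0), 1.0))


def storey_qvalues(
    p_values: Iterable[float], lambdas: np.ndarray | None = None
) -> np.ndarray:
    """Storey q-values, returned in the input order.

    q(p_(i)) = min_{j >= i} pi0 * m * p_(j) / j over the sorted p-values,
    with pi0 from :func:`estimate_pi0`; all q <= 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    pi0 = estimate_pi0(p, lambdas=lambdas)
    m = p.size
    order = np.argsort(p, kind="stable")
    ps = p[order]
    q_sorted = pi0 * m * ps / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# model / results


def call_smgs(
    frame: pd.DataFrame, p_threshold: float = 0.01, q_threshold: float = 0.25
) -> pd.DataFrame:
    """(Re)apply the significance call: tested AND p < P AND q < Q."""
    out = frame.copy()
    out["significant"] = (
        out["tested"]
        & (out["p_value"] < p_threshold)
        & (out["q_value"] < q_threshold)
    )
    return out


def differential_extract(
    target: "SmgResults | pd.DataFrame",
    counterpart: "SmgResults | pd.DataFrame",
    fold: float = 10.0,
    pvalue_floor: float = PVALUE_FLOOR,
) -> pd.DataFrame:
    """Genes significant in the target cohort whose counterpart p-value is
    at least ``fold`` times larger.

    Returns a frame indexed by gene with columns ``p_in``, ``p_out`` and
    ``log10_ratio`` (= log10 p_out - log10 p_in, after flooring both p-values
    at ``pvalue_floor``), sorted by descending ratio.
    """
    if fold <= 0:
        raise ValueError("fold must be positive")
    t = target.frame if isinstance(target, SmgResults) else target
    c = counterpart.frame if isinstance(counterpart, SmgResults) else counterpart
    sig = t.index[t["significant"]]
    missing = sig.difference(c.index)
    if len(missing):
        raise ValueError(
            f"counterpart p-values missing for {len(missing)} significant genes "
            f"(e.g. {list(missing[:5])})"
        )
    p_in = t.loc[sig, "p_value"].clip(lower=pvalue_floor)
    p_out = c.loc[sig, "p_value"].clip(lower=pvalue_floor)
    log10_ratio = np.log10(p_out) - np.log10(p_in)
    keep = log10_ratio >= np.log10(fold)
    out = pd.DataFrame(
        {"p_in": p_in[keep], "p_out": p_out[keep], "log10_ratio": log10_ratio[keep]}
    )
    out.index.name = "gene"
    return out.sort_values("log10_ratio", ascending=False)


class SmgModel:
    """Length-normalized significantly-mutated-gene model for one cohort.

    Parameters
    ----------
    counts : mapping gene -> observed protein-altering mutation count.
    gene_lengths : mapping gene -> coding length in bp. Every gene in this
        table is scored (genes absent from ``counts`` get an observed count
        of zero); every counted gene must appear here.
    method : ``'conditional_exact'`` or ``'poisson_tail'``.
    """

    def __init__(
        self,
        counts: Mapping[str, int],
        gene_lengths: Mapping[str, int],
        method: str = "conditional_exact",
    ) -> None:
        if method not in ("conditional_exact", "poisson_tail"):
            raise ValueError(f"unknown test method {method!r}")
        self.counts = dict(counts)
        self.gene_lengths = dict(gene_lengths)
        self.method = method
        self.background = background_rate(self.counts, self.gene_lengths)

    @classmethod
    def from_cohort(
        cls,
        mutations: Iterable[MutationRecord],
        cohort: Iterable[str],
        gene_lengths: Mapping[str, int],
        method: str = "conditional_exact",
        unit: str = "sample_site",
    ) -> "SmgModel":
        """Build the model from raw mutation records and a sample set."""
        counts = count_nonsynonymous(mutations, cohort, unit=unit)
        return cls(counts, gene_lengths, method=method)

    def fit(
        self, p_threshold: float = 0.01, q_threshold: float = 0.25
    ) -> "SmgResults":
        genes = sorted(self.gene_lengths)
        lengths = np.array([self.gene_lengths[g] for g in genes], dtype=int)
        observed = np.array([self.counts.get(g, 0) for g in genes], dtype=int)
        bg = self.background
        expected = bg.rate_per_bp * lengths
        if self.method == "conditional_exact":
            pi0 = lengths / bg.total_length_bp
            p = stats.binom.sf(observed - 1, bg.total_mutations, pi0)
        else:
            p = stats.poisson.sf(observed - 1, expected)
        p = np.clip(p, 0.0, 1.0)
        p[observed == 0] = 1.0
        q = storey_qvalues(p)
        frame = pd.DataFrame(
            {
                "observed": observed,
                "length_bp": lengths,
                "expected": expected,
                "p_value": p,
                "q_value": q,
                "tested": observed > expected,
            },
            index=pd.Index(genes, name="gene"),
        )
        frame = call_smgs(frame, p_threshold, q_threshold)
        return SmgResults(
            frame, bg, self.method, p_threshold=p_threshold, q_threshold=q_threshold
        )


class SmgResults:
    """Fitted per-gene results: counts, expectations, p/q-values, calls."""

    def __init__(
        self,
        frame: pd.DataFrame,
        background: BackgroundModel,
        method: str,
        p_threshold: float,
        q_threshold: float,
    ) -> None:
        self.frame = frame
        self.background = background
        self.method = method
        self.p_threshold = p_threshold
        self.q_threshold = q_threshold

    @property
    def significant_genes(self) -> list[str]:
        return list(self.frame.index[self.frame["significant"]])

    def compare(
        self, counterpart: "SmgResults", fold: float = 10.0
    ) -> pd.DataFrame:
        """Differential extraction against a counterpart cohort's results."""
        return differential_extract(self, counterpart, fold=fold)

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t")

    def summary(self, top: int = 10) -> str:
        bg = self.background
        frame = self.frame.sort_values("p_value")
        lines = [
            "Significantly mutated genes",
            "=" * 64,
            f"method:            {self.method}",
            f"genes scored:      {len(frame)}",
            f"total mutations:   {bg.total_mutations}",
            f"total length (bp): {bg.total_length_bp}",
            f"background rate:   {bg.rate_per_bp:.4g} per bp",
            f"thresholds:        p < {self.p_threshold}, q < {self.q_threshold}",
            f"significant genes: {int(frame['significant'].sum())}",
            "-" * 64,
        ]
        head = frame.head(top)[
            ["observed", "expected", "p_value", "q_value", "significant"]
        ]
        lines.append(head.to_string(float_format=lambda v: f"{v:.3g}"))
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - convenience only
        return (
            f"<SmgResults: {len(self.frame)} genes, "
            f"{int(self.frame['significant'].sum())} significant>"
        )
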