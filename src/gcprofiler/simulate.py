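"""Synthetic cohort generator with planted ground truth.

Emulates the structure of a subtype-stratified gastric-cancer cohort so that
every pipeline stage has a recovery test without any external download:

* samples laid out on a Lauren x molecular cross-table (defaults reproduce
  the study margins: 289 sequenced cases — 67 diffuse / 192 intestinal /
  19 mixed / 11 unknown, 55 GS / 234 non-GS, 39 diffuse-and-GS);
* per-sample mutation burdens drawn negative-binomially and allocated to
  genes multinomially with probability proportional to coding length, times
  a planted rate multiplier for driver genes in the sample's cohort(s);
* SNV contexts drawn from a planted per-subtype signature mixture over a
  reference catalog (half the records are emitted on the purine strand to
  exercise the reverse-complement classification path); ~10% of events are
  frameshift indels without context;
* a two-module interaction graph over the planted driver sets.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from .contexts import CONTEXT_LABELS, revcomp
from .signatures import synthetic_catalog

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_module_graph",
    "write_cohort",
    "end_to_end_recovery",
]

#: Lauren x molecular cell counts matching the study's sequenced-case margins
STUDY_CELLS: dict[tuple[str, str], int] = {
    ("diffuse", "GS"): 39,
    ("diffuse", "CIN"): 14,
    ("diffuse", "MSI"): 10,
    ("diffuse", "EBV"): 4,
    ("intestinal", "GS"): 10,
    ("intestinal", "CIN"): 110,
    ("intestinal", "MSI"): 48,
    ("intestinal", "EBV"): 24,
    ("mixed", "GS"): 4,
    ("mixed", "CIN"): 12,
    ("mixed", "MSI"): 2,
    ("mixed", "EBV"): 1,
    ("unknown", "GS"): 2,
    ("unknown", "CIN"): 6,
    ("unknown", "MSI"): 2,
    ("unknown", "EBV"): 1,
}

_DEFAULT_MIX: dict[str, dict[str, float]] = {
    # signatures common to every subtype plus one GS-distinguishing profile,
    # mirroring a shared-backbone / subtype-specific mixture structure
    "default": {
        "Signature 1": 0.4,
        "Signature 6": 0.2,
        "Signature 15": 0.1,
        "Signature 17": 0.2,
        "Signature 21": 0.1,
    },
    "GS": {
        "Signature 1": 0.4,
        "Signature 6": 0.2,
        "Signature 15": 0.1,
        "Signature 17": 0.2,
        "Signature 28": 0.1,
    },
}


def _default_drivers() -> list[tuple[str, str, float]]:
    drivers = [(f"G{i:04d}", "diffuse", 8.0) for i in range(1, 5)]
    drivers += [(f"G{i:04d}", "gs", 8.0) for i in range(5, 9)]
    # two shared drivers planted in both cohorts (CDH1/RHOA-like role)
    drivers += [("G0009", "diffuse", 8.0), ("G0009", "gs", 8.0)]
    drivers += [("G0010", "diffuse", 8.0), ("G0010", "gs", 8.0)]
    return drivers


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the study-scale conditions."""

    cells: dict[tuple[str, str], int] = field(
        default_factory=lambda: dict(STUDY_CELLS)
    )
    n_genes: int = 1000
    length_log_median: float = 1500.0  # bp; lognormal median
    length_log_sd: float = 0.6
    min_gene_length: int = 150
    muts_per_sample_mean: float = 20.0
    muts_per_sample_dispersion: float = 2.0  # NB size; var = mu + mu^2/size
    indel_fraction: float = 0.10
    drivers: list[tuple[str, str, float]] = field(default_factory=_default_drivers)
    driver_length: int | None = 2700  # bp; CDH1-like CDS, None = lognormal draw
    signature_mix: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_MIX.items()}
    )
    p_within: float = 0.6
    p_between: float = 0.05
    hypermutator: bool = False
    hypermutator_burden: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for cohort_mix in self.signature_mix.values():
            total = sum(cohort_mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"signature mixture weights must sum to 1, got {total}")
        for gene, cohort, mult in self.drivers:
            if mult < 1.0:
                raise ValueError(f"driver multiplier for {gene} must be >= 1")
            if cohort not in ("diffuse", "gs", "non_diffuse", "non_gs"):
                raise ValueError(f"unknown driver target cohort {cohort!r}")
        if not 0.0 <= self.indel_fraction <= 1.0:
            raise ValueError("indel fraction must lie in [0,1]")
        for p in (self.p_within, self.p_between):
            if not 0.0 <= p <= 1.0:
                raise ValueError("edge probabilities must lie in [0,1]")

    @property
    def n_samples(self) -> int:
        return sum(self.cells.values())

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        """Load a config from a key: value YAML file (documented schema).

        ``cells`` is written as nested ``lauren -> molecular -> n`` mappings;
        ``drivers`` as a list of ``[gene, cohort, multiplier]`` triples.
        """
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "cells" in raw:
            raw["cells"] = {
                (lauren, mol): int(n)
                for lauren, inner in raw["cells"].items()
                for mol, n in inner.items()
            }
        if "drivers" in raw:
            raw["drivers"] = [(g, c, float(m)) for g, c, m in raw["drivers"]]
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        cells: dict[str, dict[str, int]] = {}
        for (lauren, mol), n in self.cells.items():
            cells.setdefault(lauren, {})[mol] = n
        data["cells"] = cells
        data["drivers"] = [list(d) for d in self.drivers]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass
class GroundTruth:
    """What was planted: drivers per cohort, mixtures, network modules."""

    drivers: dict[str, dict[str, float]]  # cohort -> gene -> multiplier
    signature_mix: dict[str, dict[str, float]]  # molecular subtype -> mixture
    modules: dict[str, str]  # gene -> module label

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


@dataclass
class SimulatedCohort:
    """In-memory result of one simulation: the five tables plus the truth."""

    mutations: pd.DataFrame
    clinical: pd.DataFrame
    gene_lengths: pd.DataFrame
    edges: pd.DataFrame
    truth: GroundTruth
    config: SimulationConfig


def _sample_in_cohort(lauren: str, molecular: str, cohort: str) -> bool:
    return {
        "diffuse": lauren == "diffuse",
        "non_diffuse": lauren == "intestinal",
        "gs": molecular == "GS",
        "non_gs": molecular != "GS",
    }[cohort]


def simulate_module_graph(
    genes_a: list[str],
    genes_b: list[str],
    p_within: float,
    p_between: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Two-module random graph over two gene lists with scored edges.

    Genes present in both lists belong to both modules; their edges to either
    module are drawn at the within-module probability. Scores are uniform on
    [0.4, 1.0] (the medium-to-high STRING confidence range).
    """
    genes = sorted(set(genes_a) | set(genes_b))
    set_a, set_b = set(genes_a), set(genes_b)
    rows = []
    for i, u in enumerate(genes):
        for v in genes[i + 1 :]:
            same = (u in set_a and v in set_a) or (u in set_b and v in set_b)
            p = p_within if same else p_between
            if rng.random() < p:
                rows.append(
                    {"gene_a": u, "gene_b": v, "score": round(rng.uniform(0.4, 1.0), 3)}
                )
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"])


def simulate_cohort(
    config: SimulationConfig | None = None,
    catalog: pd.DataFrame | None = None,
) -> SimulatedCohort:
    """Generate all pipeline inputs with planted ground truth."""
    config = config if config is not None else SimulationConfig()
    catalog = catalog if catalog is not None else synthetic_catalog()
    rng = np.random.default_rng(config.seed)

    genes = [f"G{i:04d}" for i in range(1, config.n_genes + 1)]
    bad = [g for g, _, _ in config.drivers if g not in set(genes)]
    if bad:
        raise ValueError(f"driver genes not in the simulated gene set: {bad}")
    lengths = np.exp(
        rng.normal(math.log(config.length_log_median), config.length_log_sd, config.n_genes)
    ).astype(int)
    lengths = np.maximum(lengths, config.min_gene_length)
    if config.driver_length is not None:
        # planted drivers get a fixed, driver-typical coding length so that
        # detection power is governed by the planted multiplier, not by the
        # length lottery of the lognormal draw
        idx = {g: j for j, g in enumerate(genes)}
        for g, _, _ in config.drivers:
            lengths[idx[g]] = config.driver_length
    offsets = np.concatenate([[0], np.cumsum(lengths)[:-1]])  # chrS block starts

    # clinical labels
    samples: list[tuple[str, str, str]] = []
    i = 0
    for (lauren, mol), n in sorted(config.cells.items()):
        for _ in range(n):
            i += 1
            samples.append((f"S{i:04d}", lauren, mol))
    clinical = pd.DataFrame(samples, columns=["sample", "lauren", "molecular"])

    # per-cohort driver multipliers as weight vectors
    gene_index = {g: j for j, g in enumerate(genes)}
    driver_map: dict[str, dict[str, float]] = {}
    for gene, cohort, mult in config.drivers:
        driver_map.setdefault(cohort, {})
        driver_map[cohort][gene] = max(driver_map[cohort].get(gene, 1.0), mult)

    mix_names = sorted(catalog.columns)
    catalog_probs = {name: catalog[name].to_numpy(dtype=float) for name in mix_names}

    nb_size = config.muts_per_sample_dispersion
    hyper_sample = samples[0][0] if config.hypermutator else None

    rows: list[tuple] = []
    for sample_id, lauren, mol in samples:
        mean = (
            config.hypermutator_burden
            if sample_id == hyper_sample
            else config.muts_per_sample_mean
        )
        n_mut = int(rng.negative_binomial(nb_size, nb_size / (nb_size + mean)))
        if n_mut == 0:
            continue
        mult = np.ones(config.n_genes)
        for cohort, gene_mults in driver_map.items():
            if _sample_in_cohort(lauren, mol, cohort):
                for g, m in gene_mults.items():
                    # a driver planted in several cohorts is elevated at its
                    # multiplier in samples of any of them, not at the product
                    j = gene_index[g]
                    mult[j] = max(mult[j], m)
        weights = lengths * mult
        weights = weights / weights.sum()
        gene_idx = rng.choice(config.n_genes, size=n_mut, p=weights)
        is_indel = rng.random(n_mut) < config.indel_fraction

        mixture = config.signature_mix.get(mol, config.signature_mix["default"])
        mix_keys = sorted(mixture)
        mix_w = np.array([mixture[k] for k in mix_keys])
        sig_choice = rng.choice(len(mix_keys), size=n_mut, p=mix_w)

        for j in range(n_mut):
            g = gene_idx[j]
            pos = int(offsets[g] + rng.integers(1, lengths[g] + 1))
            if is_indel[j]:
                ref = "ACGT"[rng.integers(4)]
                rows.append(
                    (sample_id, genes[g], "frameshift_indel", "chrS", pos, ref, "-", "")
                )
                continue
            probs = catalog_probs[mix_keys[sig_choice[j]]]
            cat = int(rng.choice(96, p=probs))
            label = CONTEXT_LABELS[cat]
            five, ref, alt, three = label[0], label[2], label[4], label[6]
            context = f"{five}{ref}{three}"
            if rng.random() < 0.5:  # emit on the purine strand
                ref, alt, context = revcomp(ref), revcomp(alt), revcomp(context)
            rows.append((sample_id, genes[g], "missense", "chrS", pos, ref, alt, context))

    mutations = pd.DataFrame(
        rows, columns=["sample", "gene", "class", "chrom", "pos", "ref", "alt", "context"]
    )

    module_a = sorted(driver_map.get("diffuse", {}))
    module_b = sorted(driver_map.get("gs", {}))
    edges = simulate_module_graph(
        module_a, module_b, config.p_within, config.p_between, rng
    )

    truth = GroundTruth(
        drivers={c: dict(sorted(m.items())) for c, m in sorted(driver_map.items())},
        signature_mix={
            mol: dict(config.signature_mix.get(mol, config.signature_mix["default"]))
            for mol in ("EBV", "MSI", "GS", "CIN")
        },
        modules={
            **{g: "A" for g in module_a},
            **{g: "B" for g in module_b if g not in module_a},
        },
    )
    gene_lengths = pd.DataFrame({"gene": genes, "coding_length_bp": lengths})
    return SimulatedCohort(mutations, clinical, gene_lengths, edges, truth, config)


def write_cohort(sim: SimulatedCohort, outdir: str | Path) -> dict[str, Path]:
    """Write the five inputs plus ground truth to ``outdir``; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mutations": outdir / "mutations.tsv",
        "clinical": outdir / "clinical.tsv",
        "gene_lengths": outdir / "gene_lengths.tsv",
        "edges": outdir / "edges.tsv",
        "truth": outdir / "ground_truth.json",
    }
    sim.mutations.to_csv(paths["mutations"], sep="\t", index=False)
    sim.clinical.to_csv(paths["clinical"], sep="\t", index=False)
    sim.gene_lengths.to_csv(paths["gene_lengths"], sep="\t", index=False)
    sim.edges.to_csv(paths["edges"], sep="\t", index=False)
    sim.truth.to_json(paths["truth"])
    return paths


# ---------------------------------------------------------------------------
# end-to-end recovery


def end_to_end_recovery(
    config: SimulationConfig | None = None,
    catalog: pd.DataFrame | None = None,
    p_threshold: float = 0.01,
    q_threshold: float = 0.25,
    fold: float = 10.0,
    min_score: float = 0.4,
) -> dict:
    """Run the full pipeline on a simulated cohort and score it against truth.

    Returns a report with driver sensitivity and observed false-discovery
    rate, shared-driver detection, differential-set sizes and disjointness,
    network paired-t p-values, and the cosine of each pooled cohort spectrum
    against its planted mixture profile.
    """
    from . import io as io_mod
    from .network import NetworkPartition
    from .signatures import build_spectrum, cosine_similarity
    from .smg import SmgModel, differential_extract

    config = config if config is not None else SimulationConfig()
    catalog = catalog if catalog is not None else synthetic_catalog()
    sim = simulate_cohort(config, catalog)

    labels = [
        io_mod.SampleLabel(r["sample"], r["lauren"], r["molecular"])
        for _, r in sim.clinical.iterrows()
    ]
    sequenced = {l.sample_id for l in labels}
    part = io_mod.partition_cohorts(labels, sequenced)
    lengths = dict(zip(sim.gene_lengths["gene"], sim.gene_lengths["coding_length_bp"]))
    records = [
        io_mod.MutationRecord(
            r["sample"], r["gene"], r["class"], r["chrom"], int(r["pos"]),
            r["ref"], r["alt"], r["context"] if r["context"] else None,
        )
        for _, r in sim.mutations.iterrows()
    ]

    results = {
        name: SmgModel.from_cohort(records, cohort, lengths).fit(
            p_threshold, q_threshold
        )
        for name, cohort in part.as_dict().items()
    }
    diff_diffuse = differential_extract(
        results["diffuse"], results["non_diffuse"], fold=fold
    )
    diff_gs = differential_extract(results["gs"], results["non_gs"], fold=fold)

    truth = sim.truth
    planted = {c: set(t) for c, t in truth.drivers.items()}
    planted_any = set().union(*planted.values()) if planted else set()
    report: dict = {}
    tp = fp = hits = planted_total = 0
    for name in ("diffuse", "gs"):
        truth_set = planted.get(name, set())
        called = set(results[name].significant_genes)
        hits += len(called & truth_set)
        planted_total += len(truth_set)
        # a call is false only if the gene was planted nowhere: with
        # overlapping cohorts a driver planted in the paired subtype is
        # genuinely rate-elevated here too
        tp += len(called & planted_any)
        fp += len(called - planted_any)
    report["sensitivity"] = hits / planted_total if planted_total else math.nan
    report["fdr"] = fp / (tp + fp) if (tp + fp) else 0.0

    shared = planted.get("diffuse", set()) & planted.get("gs", set())
    in_both = set(diff_diffuse.index) & set(diff_gs.index)
    report["n_differential_diffuse"] = len(diff_diffuse)
    report["n_differential_gs"] = len(diff_gs)
    report["shared_planted"] = sorted(shared)
    report["shared_detected"] = sorted(shared & in_both)
    report["differential_overlap"] = sorted(in_both)

    if len(diff_diffuse) and len(diff_gs) and len(sim.edges):
        net = NetworkPartition(
            sim.edges,
            set(diff_diffuse.index),
            set(diff_gs.index),
            min_score=min_score,
            labels=("diffuse", "gs"),
        ).fit()
        report["network"] = net.to_dict()

    spectra_cosines = {}
    for name, cohort in part.as_dict().items():
        spec = build_spectrum(records, cohort, granularity="per_cohort", row_id=name)
        pooled = spec.counts.iloc[0].to_numpy(dtype=float)
        if pooled.sum() == 0:
            continue
        # mixture-weighted expected profile for this cohort's samples
        mols = [l.molecular for l in labels if l.sample_id in cohort]
        profile = np.zeros(len(CONTEXT_LABELS))
        for mol in mols:
            mixture = config.signature_mix.get(mol, config.signature_mix["default"])
            for sig, w in mixture.items():
                profile += w * catalog[sig].to_numpy(dtype=float)
        spectra_cosines[name] = cosine_similarity(pooled, profile)
    report["spectrum_cosine_vs_truth"] = spectra_cosines
    return report
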