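"""Input tables and cohort partitioning.

Readers for the five tabular inputs of the pipeline — somatic mutation calls
(a MAF-style TSV or a simple TSV), clinical subtype labels, gene coding
lengths, interaction edges, and a reference signature catalog — plus the
cohort partition rules used throughout:

* Lauren histopathology: ``diffuse`` vs. ``non-diffuse``, where non-diffuse
  contains only samples labelled ``intestinal`` (mixed/unknown are excluded
  from the comparator, not re-assigned);
* molecular subtype: ``GS`` (genomically stable) vs. ``non-GS`` (everything
  else that was sequenced).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .contexts import CONTEXT_LABELS

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# vocabulary

#: protein-altering classes counted toward significantly-mutated-gene tests
NONSYNONYMOUS_CLASSES = frozenset(
    {"missense", "nonsense", "frameshift_indel", "inframe_indel", "splice_site"}
)

VARIANT_CLASSES = NONSYNONYMOUS_CLASSES | {"silent", "other_noncoding"}

INDEL_CLASSES = frozenset({"frameshift_indel", "inframe_indel"})

#: MAF Variant_Classification vocabulary -> internal classes
MAF_CLASS_MAP = {
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "nonsense",
    "Nonstop_Mutation": "nonsense",
    "Frame_Shift_Del": "frameshift_indel",
    "Frame_Shift_Ins": "frameshift_indel",
    "In_Frame_Del": "inframe_indel",
    "In_Frame_Ins": "inframe_indel",
    "Splice_Site": "splice_site",
    "Silent": "silent",
}

LAUREN_TYPES = ("diffuse", "intestinal", "mixed", "unknown")
MOLECULAR_SUBTYPES = ("EBV", "MSI", "GS", "CIN")


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class MutationRecord:
    """One somatic variant call.

    ``context3`` is the reference-strand trinucleotide centred on ``pos``;
    it may be ``None`` (e.g. for indels), in which case the record cannot be
    placed in the 96-category substitution matrix.
    """

    sample_id: str
    gene: str
    variant_class: str
    chrom: str
    pos: int
    ref: str
    alt: str
    context3: str | None = None

    def __post_init__(self) -> None:
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant class {self.variant_class!r}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles are identical ({self.ref!r})")

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref) == 1
            and len(self.alt) == 1
            and self.ref in "ACGT"
            and self.alt in "ACGT"
            and self.variant_class not in INDEL_CLASSES
        )


@dataclass(frozen=True)
class SampleLabel:
    sample_id: str
    lauren: str
    molecular: str

    def __post_init__(self) -> None:
        if self.lauren not in LAUREN_TYPES:
            raise ValueError(f"unknown Lauren type {self.lauren!r}")
        if self.molecular not in MOLECULAR_SUBTYPES:
            raise ValueError(f"unknown molecular subtype {self.molecular!r}")


@dataclass(frozen=True)
class GeneModel:
    gene: str
    coding_length_bp: int

    def __post_init__(self) -> None:
        if self.coding_length_bp <= 0:
            raise ValueError(
                f"coding length for {self.gene} must be positive, "
                f"got {self.coding_length_bp}"
            )


@dataclass
class CohortPartition:
    """The four sample sets compared throughout the analysis."""

    diffuse: frozenset = field(default_factory=frozenset)
    non_diffuse: frozenset = field(default_factory=frozenset)
    gs: frozenset = field(default_factory=frozenset)
    non_gs: frozenset = field(default_factory=frozenset)

    def as_dict(self) -> dict[str, frozenset]:
        return {
            "diffuse": self.diffuse,
            "non_diffuse": self.non_diffuse,
            "gs": self.gs,
            "non_gs": self.non_gs,
        }


# ---------------------------------------------------------------------------
# readers

_MAF_COLUMNS = {
    "sample": "Tumor_Sample_Barcode",
    "gene": "Hugo_Symbol",
    "class": "Variant_Classification",
    "chrom": "Chromosome",
    "pos": "Start_Position",
    "ref": "Reference_Allele",
    "alt": "Tumor_Seq_Allele2",
}
_SIMPLE_COLUMNS = {
    "sample": "sample",
    "gene": "gene",
    "class": "class",
    "chrom": "chrom",
    "pos": "pos",
    "ref": "ref",
    "alt": "alt",
}


def _normalize_class(raw: str) -> str | None:
    if raw in VARIANT_CLASSES:
        return raw
    return MAF_CLASS_MAP.get(raw)


def read_mutations(path: str | Path, dialect: str = "maf") -> list[MutationRecord]:
    """Read a mutation table into :class:`MutationRecord` rows.

    ``dialect='maf'`` expects the conventional MAF columns (tab-separated,
    1-based coordinates, ``#`` comment lines skipped); ``dialect='simple_tsv'``
    expects headers ``sample, gene, class, chrom, pos, ref, alt`` with an
    optional ``context`` column. Classification values outside the known
    vocabulary are mapped to ``other_noncoding`` and counted in the log.
    """
    if dialect not in ("maf", "simple_tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    colmap = _MAF_COLUMNS if dialect == "maf" else _SIMPLE_COLUMNS
    df = pd.read_csv(
        path,
        sep="\t",
        dtype=str,
        comment="#" if dialect == "maf" else None,
        keep_default_na=False,
    )
    for role, col in colmap.items():
        if col not in df.columns:
            raise ValueError(f"mutation table {path} is missing required column {col!r}")
    context_col = next(
        (c for c in ("context", "ref_context", "Ref_Context") if c in df.columns), None
    )

    records: list[MutationRecord] = []
    unmapped: Counter[str] = Counter()
    for i, values in enumerate(df.itertuples(index=False, name=None), start=2):
        row = dict(zip(df.columns, values))  # header = line 1
        raw_pos = row[colmap["pos"]]
        try:
            pos = int(raw_pos)
        except (TypeError, ValueError):
            raise ValueError(
                f"malformed position {raw_pos!r} at data row {i} of {path}"
            ) from None
        raw_class = row[colmap["class"]]
        vclass = _normalize_class(raw_class)
        if vclass is None:
            unmapped[raw_class] += 1
            vclass = "other_noncoding"
        context = row.get(context_col) if context_col else None
        if context in ("", "NA", "."):
            context = None
        try:
            records.append(
                MutationRecord(
                    sample_id=row[colmap["sample"]],
                    gene=row[colmap["gene"]],
                    variant_class=vclass,
                    chrom=row[colmap["chrom"]],
                    pos=pos,
                    ref=row[colmap["ref"]],
                    alt=row[colmap["alt"]],
                    context3=context,
                )
            )
        except ValueError as exc:
            raise ValueError(f"invalid mutation at data row {i} of {path}: {exc}") from None
    if unmapped:
        logger.warning(
            "%d rows with unmappable variant classification mapped to other_noncoding: %s",
            sum(unmapped.values()),
            dict(unmapped),
        )
    return records


def read_clinical(path: str | Path) -> list[SampleLabel]:
    """Read the clinical label TSV (headers ``sample, lauren, molecular``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample", "lauren", "molecular"):
        if col not in df.columns:
            raise ValueError(f"clinical table {path} is missing required column {col!r}")
    dup = df["sample"][df["sample"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate sample ids in {path}: {sorted(set(dup))}")
    return [
        SampleLabel(r["sample"], r["lauren"], r["molecular"])
        for _, r in df.iterrows()
    ]


def read_gene_lengths(path: str | Path) -> dict[str, int]:
    """Read the gene-length TSV (headers ``gene, coding_length_bp``)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene", "coding_length_bp"):
        if col not in df.columns:
            raise ValueError(f"gene-length table {path} is missing required column {col!r}")
    dup = df["gene"][df["gene"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate gene symbols in {path}: {sorted(set(dup))}")
    lengths: dict[str, int] = {}
    for _, r in df.iterrows():
        gm = GeneModel(str(r["gene"]), int(r["coding_length_bp"]))  # validates > 0
        lengths[gm.gene] = gm.coding_length_bp
    return lengths


def read_edges(path: str | Path) -> nx.Graph:
    """Read an interaction edge table into an undirected scored graph.

    Accepts STRING-style headers (``protein1, protein2, combined_score`` with
    scores on the 0-1000 scale, rescaled to [0,1]) or plain
    ``gene_a, gene_b, score`` / ``geneA, geneB, score``. Self-loops are
    dropped; duplicate unordered pairs keep the maximum score.
    """
    df = pd.read_csv(path, sep="\t")
    if {"protein1", "protein2", "combined_score"} <= set(df.columns):
        a, b = df["protein1"], df["protein2"]
        score = df["combined_score"].astype(float) / 1000.0
    elif {"gene_a", "gene_b", "score"} <= set(df.columns):
        a, b = df["gene_a"], df["gene_b"]
        score = df["score"].astype(float)
    elif {"geneA", "geneB", "score"} <= set(df.columns):
        a, b = df["geneA"], df["geneB"]
        score = df["score"].astype(float)
    else:
        raise ValueError(
            f"edge table {path} needs columns protein1/protein2/combined_score "
            "or gene_a/gene_b/score"
        )
    if ((score < 0) | (score > 1)).any():
        raise ValueError(f"edge scores in {path} fall outside [0,1] after rescaling")
    graph = nx.Graph()
    n_self = 0
    for u, v, s in zip(a.astype(str), b.astype(str), score):
        if u == v:
            n_self += 1
            continue
        if graph.has_edge(u, v):
            graph[u][v]["score"] = max(graph[u][v]["score"], float(s))
        else:
            graph.add_edge(u, v, score=float(s))
    if n_self:
        logger.warning("dropped %d self-loop edges from %s", n_self, path)
    return graph


def read_catalog(path: str | Path) -> pd.DataFrame:
    """Read a 96-context reference signature catalog TSV.

    The first column holds the context labels (``"A[C>A]A"`` style); each
    remaining column is one signature. Rows are reindexed to the canonical
    category order and columns are renormalized to sum to one (with a warning
    if they were off by more than 1e-6).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(CONTEXT_LABELS) - set(df.index)
    if missing:
        raise ValueError(
            f"catalog {path} is missing {len(missing)} context rows "
            f"(e.g. {sorted(missing)[:3]})"
        )
    df = df.loc[list(CONTEXT_LABELS)].astype(float)
    sums = df.sum(axis=0)
    if (sums <= 0).any():
        raise ValueError(f"catalog {path} has non-positive signature columns")
    if (sums - 1.0).abs().max() > 1e-6:
        logger.warning("catalog %s columns renormalized to sum to 1", path)
    return df / sums


# ---------------------------------------------------------------------------
# partitioning and counting


def partition_cohorts(
    labels: Iterable[SampleLabel], sequenced: Iterable[str]
) -> CohortPartition:
    """Split sequenced samples into the four analysis cohorts.

    ``diffuse`` / ``non_diffuse`` follow the Lauren classification with
    mixed/unknown excluded from the non-diffuse comparator; ``gs`` /
    ``non_gs`` split every sequenced sample by molecular subtype.
    """
    labels = list(labels)
    seen: Counter[str] = Counter(l.sample_id for l in labels)
    dups = sorted(s for s, n in seen.items() if n > 1)
    if dups:
        raise ValueError(f"duplicate sample ids in labels: {dups}")
    sequenced = frozenset(sequenced)
    unlabeled = sequenced - set(seen)
    if unlabeled:
        raise ValueError(
            f"{len(unlabeled)} sequenced samples have no clinical label "
            f"(e.g. {sorted(unlabeled)[:3]})"
        )
    by_lauren: dict[str, set[str]] = {t: set() for t in LAUREN_TYPES}
    gs: set[str] = set()
    for lab in labels:
        if lab.sample_id not in sequenced:
            continue
        by_lauren[lab.lauren].add(lab.sample_id)
        if lab.molecular == "GS":
            gs.add(lab.sample_id)
    return CohortPartition(
        diffuse=frozenset(by_lauren["diffuse"]),
        non_diffuse=frozenset(by_lauren["intestinal"]),
        gs=frozenset(gs),
        non_gs=frozenset(sequenced - gs),
    )


def count_nonsynonymous(
    muts: Iterable[MutationRecord],
    cohort: Iterable[str],
    unit: str = "sample_site",
) -> dict[str, int]:
    """Count protein-altering mutation events per gene within a cohort.

    Only records whose class is in :data:`NONSYNONYMOUS_CLASSES` and whose
    sample belongs to ``cohort`` are counted. ``unit='sample_site'`` (default)
    counts each (sample, gene, pos, ref, alt) event once — a hotspot recurrent
    in k samples contributes k. ``unit='unique_site'`` collapses identical
    sites across samples to a single count.
    """
    if unit not in ("sample_site", "unique_site"):
        raise ValueError(f"unknown counting unit {unit!r}")
    cohort = frozenset(cohort)
    seen: set[tuple] = set()
    counts: dict[str, int] = {}
    for rec in muts:
        if rec.sample_id not in cohort:
            continue
        if rec.variant_class not in NONSYNONYMOUS_CLASSES:
            continue
        key = (rec.gene, rec.pos, rec.ref, rec.alt)
        if unit == "sample_site":
            key = (rec.sample_id, *key)
        if key in seen:
            continue
        seen.add(key)
        counts[rec.gene] = counts.get(rec.gene, 0) + 1
    return counts


def drop_unlabeled(
    muts: Iterable[MutationRecord], labels: Iterable[SampleLabel]
) -> list[MutationRecord]:
    """Drop mutation records whose sample has no clinical label (warn, keep rest)."""
    muts = list(muts)
    labeled = {l.sample_id for l in labels}
    kept = [m for m in muts if m.sample_id in labeled]
    dropped = {m.sample_id for m in muts if m.sample_id not in labeled}
    if dropped:
        logger.warning(
            "dropped %d mutation rows from %d unlabeled samples",
            len(muts) - len(kept),
            len(dropped),
        )
    return kept
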