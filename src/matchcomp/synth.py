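"""Synthetic genomes, annotations and GO mappings with controlled structure.

Everything downstream of the index — null-distribution checks, interval
calling, promoter counting, GO enrichment — is exercised on data built here:
i.i.d. random genomes of chosen GC content, exact repeat copies planted to
create low-complexity regions, and gene/GO annotations in which chosen
categories are enriched inside given (typically high-complexity) intervals.
All generators are pure functions of their arguments and a seed, and the
writers emit the standard FASTA / refGene / gene_info / gene2go formats so
fixtures flow through the production readers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotate import GeneModel, GoMapping, PROMOTER_HALF_BEFORE, PROMOTER_HALF_AFTER
from .esa import SequenceSet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class RepeatPlan:
    """Copy [source_start, source_end] (1-based incl.) to each target start."""

    source_start: int
    source_end: int
    targets: tuple[int, ...]

    @property
    def length(self) -> int:
        return self.source_end - self.source_start + 1


@dataclass(frozen=True)
class CategorySpec:
    """A GO category of ``size`` genes; ``enriched_fraction`` of them get
    promoters inside the supplied unique intervals, the rest are uniform."""

    name: str
    size: int
    enriched_fraction: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.enriched_fraction <= 1.0):
            raise ValueError("enriched_fraction must lie in [0, 1]")


@dataclass
class SynthSpec:
    """Full recipe for a synthetic study: genome, repeats, genes, GO plan."""

    total_length: int
    gc: float = 0.5
    seed: int = 0
    repeats: list[RepeatPlan] = field(default_factory=list)
    categories: list[CategorySpec] = field(default_factory=list)
    identifier: str = "synth1"


def random_genome(
    length: int, gc: float, seed: int, identifier: str = "synth1"
) -> SequenceSet:
    """I.i.d. random sequence with P(C) = P(G) = gc/2, reproducible per seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not (0.0 < gc < 1.0):
        raise ValueError("gc must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    p = gc / 2.0
    q = 0.5 - p
    codes = rng.choice(4, size=length, p=[q, p, p, q])
    seq = _BASES[codes].tobytes().decode("ascii")
    return SequenceSet([(identifier, seq)])


def plant_repeats(
    seqs: SequenceSet, repeats: list[RepeatPlan], identifier: str | None = None
) -> tuple[SequenceSet, list[tuple[int, int]]]:
    """Overwrite target positions with copies of the source intervals.

    Returns the modified sequence set and the provenance list of planted
    (start, end) intervals (the source intervals are repetitive too once
    copied, but only placed copies are listed).  Overlapping target
    intervals are an error.
    """
    if identifier is None:
        identifier = seqs.records[0][0]
    idx = seqs.identifiers.index(identifier)
    arr = np.frombuffer(seqs.records[idx][1].encode("ascii"), dtype=np.uint8).copy()
    n = arr.size
    placed: list[tuple[int, int]] = []
    for plan in repeats:
        if not (1 <= plan.source_start <= plan.source_end <= n):
            raise ValueError(f"source interval {plan.source_start}-{plan.source_end} out of range")
        src = arr[plan.source_start - 1 : plan.source_end].copy()
        for t in plan.targets:
            if not (1 <= t and t + plan.length - 1 <= n):
                raise ValueError(f"target {t} out of range for repeat of length {plan.length}")
            placed.append((t, t + plan.length - 1))
    placed_sorted = sorted(placed)
    for (s1, e1), (s2, e2) in zip(placed_sorted, placed_sorted[1:]):
        if s2 <= e1:
            raise ValueError(f"overlapping repeat targets: {s1}-{e1} and {s2}-{e2}")
    for plan in repeats:
        src = arr[plan.source_start - 1 : plan.source_end].copy()
        for t in plan.targets:
            arr[t - 1 : t + plan.length - 1] = src
    records = list(seqs.records)
    records[idx] = (identifier, arr.tobytes().decode("ascii"))
    return SequenceSet(records), placed


def synth_annotation(
    spec: SynthSpec,
    unique_intervals: list[tuple[str, int, int]],
    seed: int | None = None,
) -> tuple[list[GeneModel], GoMapping]:
    """Place genes per category plan and return models plus a GO mapping.

    For each category, ``enriched_fraction`` of its genes get a TSS chosen so
    the whole 4 kb promoter lies inside one of the unique intervals; the rest
    are uniform over the record (with a margin keeping promoters on-record).
    Raises when enrichment is requested but no interval can hold a promoter.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    L = spec.total_length
    rec = spec.identifier
    margin_lo = PROMOTER_HALF_BEFORE + 1
    margin_hi = L - PROMOTER_HALF_AFTER
    if margin_hi < margin_lo:
        raise ValueError("record too short to hold any promoter")
    roomy = [
        (s, e)
        for r, s, e in unique_intervals
        if r == rec and (e - PROMOTER_HALF_AFTER) >= (s + PROMOTER_HALF_BEFORE)
    ]
    genes: list[GeneModel] = []
    gene_to_go: dict[str, set[str]] = {}
    terms: dict[str, tuple[str, str]] = {}
    gnum = 0
    for cat in spec.categories:
        terms[cat.name] = (cat.name, "Process")
        n_enriched = int(round(cat.enriched_fraction * cat.size))
        if n_enriched > 0 and not roomy:
            raise ValueError(
                f"category {cat.name}: enrichment requested but no unique interval "
                "can contain a full promoter"
            )
        for k in range(cat.size):
            gnum += 1
            sym = f"G{gnum:05d}"
            if k < n_enriched:
                s, e = roomy[int(rng.integers(len(roomy)))]
                tss = int(rng.integers(s + PROMOTER_HALF_BEFORE, e - PROMOTER_HALF_AFTER + 1))
            else:
                tss = int(rng.integers(margin_lo, margin_hi + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            tx_len = int(rng.integers(1_000, 10_001))
            if strand == "+":
                tx_start, tx_end = tss, min(L, tss + tx_len)
            else:
                tx_start, tx_end = max(1, tss - tx_len), tss
            genes.append(
                GeneModel(symbol=sym, record=rec, strand=strand, tx_start=tx_start, tx_end=tx_end)
            )
            gene_to_go[sym] = {cat.name}
    return genes, GoMapping(gene_to_go=gene_to_go, terms=terms)


# ---------------------------------------------------------------------------
# Writers (standard flat formats, so fixtures use the production readers)
# ---------------------------------------------------------------------------

def write_fasta(seqs: SequenceSet, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for ident, seq in seqs.records:
            fh.write(f">{ident}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_refgene(genes: list[GeneModel], path: str | Path) -> None:
    """UCSC refGene flat dump (16 columns, leading bin; txStart 0-based)."""
    with open(path, "w") as fh:
        for k, g in enumerate(genes, start=1):
            s0 = g.tx_start - 1
            fh.write(
                "\t".join(
                    [
                        "0",
                        f"NM_{k:06d}",
                        g.record,
                        g.strand,
                        str(s0),
                        str(g.tx_end),
                        str(s0),
                        str(g.tx_end),
                        "1",
                        f"{s0},",
                        f"{g.tx_end},",
                        "0",
                        g.symbol,
                        "cmpl",
                        "cmpl",
                        "0,",
                    ]
                )
                + "\n"
            )


def _gene_ids(mapping: GoMapping) -> dict[str, int]:
    return {sym: i + 1 for i, sym in enumerate(sorted(mapping.gene_to_go))}


def write_gene_info(mapping: GoMapping, path: str | Path, tax_id: int = 9606) -> None:
    """NCBI gene_info tab format (tax_id, GeneID, Symbol, ...)."""
    ids = _gene_ids(mapping)
    with open(path, "w") as fh:
        fh.write("#tax_id\tGeneID\tSymbol\tLocusTag\tSynonyms\n")
        for sym, gid in ids.items():
            fh.write(f"{tax_id}\t{gid}\t{sym}\t-\t-\n")


def write_gene2go(mapping: GoMapping, path: str | Path, tax_id: int = 9606) -> None:
    """NCBI gene2go tab format; all synthetic categories are Process terms."""
    ids = _gene_ids(mapping)
    with open(path, "w") as fh:
        fh.write(
            "#tax_id\tGeneID\tGO_ID\tEvidence\tQualifier\tGO_term\tPubMed\tCategory\n"
        )
        for sym, gid in ids.items():
            for cat in sorted(mapping.gene_to_go[sym]):
                name = mapping.terms.get(cat, (cat, "Process"))[0]
                fh.write(f"{tax_id}\t{gid}\t{cat}\tIEA\t-\t{name}\t-\tProcess\n")
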