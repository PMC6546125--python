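"""Gene annotation of high-Cm windows and Monte-Carlo GO enrichment.

Maps qualifying windows to gene promoters (the 4 kb interval centred on the
transcription start site), estimates the gene count expected under random
window placement by Monte Carlo, and tests GO biological-process categories
for enrichment by resampling gene sets, with Bonferroni correction over the
categories actually tested.

Monte-Carlo iterations are independent: each iteration i of a run seeded
with s uses its own generator seeded from (s, i), so results are identical
whether iterations run serially, chunked or reordered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("matchcomp")

PROMOTER_HALF_BEFORE = 2000  # promoter = [TSS-2000, TSS+1999]: 4000 bases
PROMOTER_HALF_AFTER = 1999


# ---------------------------------------------------------------------------
# Gene models and file readers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """One gene (or transcript before deduplication), 1-based inclusive."""

    symbol: str
    record: str
    strand: str
    tx_start: int
    tx_end: int

    def __post_init__(self):
        if self.tx_start > self.tx_end:
            raise ValueError(f"{self.symbol}: tx_start > tx_end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.symbol}: strand must be + or -")

    @property
    def tss(self) -> int:
        """Transcription start site: tx_start on +, tx_end on -."""
        return self.tx_start if self.strand == "+" else self.tx_end


@dataclass(frozen=True)
class PromoterInterval:
    """Promoter of a gene: 4 kb centred on the TSS, clipped at record ends."""

    symbol: str
    record: str
    start: int
    end: int


@dataclass
class GoMapping:
    """Flat gene-symbol -> GO-category assignments (no graph propagation).

    Only biological_process categories are retained for testing.
    """

    gene_to_go: dict[str, set[str]]
    terms: dict[str, tuple[str, str]]  # id -> (name, namespace)

    def members(self, category: str, universe=None) -> set[str]:
        pool = self.gene_to_go if universe is None else universe
        return {g for g in pool if category in self.gene_to_go.get(g, ())}

    def annotated_genes(self) -> list[str]:
        return sorted(g for g, cats in self.gene_to_go.items() if cats)


def read_refgene(path: str | Path) -> list[GeneModel]:
    """Read a UCSC refGene flat dump; one GeneModel per transcript.

    Handles the dump with or without the leading `bin` column.  UCSC txStart
    is 0-based half-open; it is converted to 1-based inclusive here.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    ncol = df.shape[1]
    # with bin: bin name chrom strand txStart txEnd ... name2 at index 12
    if ncol >= 13 and df.iloc[:, 3].isin(["+", "-"]).all():
        chrom, strand, s, e, sym = 2, 3, 4, 5, 12
    elif df.iloc[:, 2].isin(["+", "-"]).all():
        chrom, strand, s, e, sym = 1, 2, 3, 4, 11
    else:
        raise ValueError(f"{path}: unrecognised refGene column layout")
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            GeneModel(
                symbol=row[sym],
                record=row[chrom],
                strand=row[strand],
                tx_start=int(row[s]) + 1,
                tx_end=int(row[e]),
            )
        )
    return genes


def deduplicate(genes: list[GeneModel]) -> list[GeneModel]:
    """One GeneModel per symbol: the longest transcript (ties: leftmost)."""
    best: dict[str, GeneModel] = {}
    for g in genes:
        cur = best.get(g.symbol)
        if (
            cur is None
            or (g.tx_end - g.tx_start) > (cur.tx_end - cur.tx_start)
            or ((g.tx_end - g.tx_start) == (cur.tx_end - cur.tx_start) and g.tx_start < cur.tx_start)
        ):
            best[g.symbol] = g
    return [best[s] for s in sorted(best)]


def read_gene_info(path: str | Path) -> dict[int, str]:
    """NCBI gene_info: GeneID -> Symbol (columns 2 and 3 of the tab format)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    return {int(gid): sym for gid, sym in zip(df.iloc[:, 1], df.iloc[:, 2])}


def read_gene2go(
    path: str | Path, gene_info: dict[int, str], namespace: str = "Process"
) -> GoMapping:
    """NCBI gene2go -> GoMapping of biological_process assignments.

    Columns: tax_id GeneID GO_ID Evidence Qualifier GO_term PubMed Category.
    Only rows whose Category matches ``namespace`` are kept, and only genes
    present in ``gene_info``.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    gene_to_go: dict[str, set[str]] = {}
    terms: dict[str, tuple[str, str]] = {}
    for row in df.itertuples(index=False):
        if row[7] != namespace:
            continue
        sym = gene_info.get(int(row[1]))
        if sym is None:
            continue
        go_id, go_name = row[2], row[5]
        gene_to_go.setdefault(sym, set()).add(go_id)
        terms[go_id] = (go_name, namespace)
    return GoMapping(gene_to_go=gene_to_go, terms=terms)


# ---------------------------------------------------------------------------
# Promoters and window intersection
# ---------------------------------------------------------------------------

def promoters(
    genes: list[GeneModel], record_lengths: dict[str, int] | None = None
) -> list[PromoterInterval]:
    """Promoter intervals [TSS-2000, TSS+1999], clipped to [1, record length].

    The interval is genomic and centred on the TSS regardless of strand (an
    exact 4000-base window requires the asymmetric split).  Genes whose TSS
    lies outside their record are skipped with a warning.
    """
    out = []
    for g in genes:
        limit = record_lengths.get(g.record) if record_lengths else None
        if limit is not None and not (1 <= g.tss <= limit):
            logger.warning("gene %s: TSS %d outside record %s: skipped", g.symbol, g.tss, g.record)
            continue
        start = max(1, g.tss - PROMOTER_HALF_BEFORE)
        end = g.tss + PROMOTER_HALF_AFTER
        if limit is not None:
            end = min(end, limit)
        out.append(PromoterInterval(symbol=g.symbol, record=g.record, start=start, end=end))
    return out


def _window_triples(windows) -> list[tuple[str, int, int]]:
    if isinstance(windows, pd.DataFrame):
        return list(zip(windows["record"], windows["start"].astype(int), windows["end"].astype(int)))
    return [(w[0], int(w[1]), int(w[2])) for w in windows]


def _overlap_matrix(proms: list[PromoterInterval], windows) -> list[np.ndarray]:
    """Per-window arrays of promoter indices sharing >= 1 base."""
    triples = _window_triples(windows)
    by_rec: dict[str, list[int]] = {}
    for k, p in enumerate(proms):
        by_rec.setdefault(p.record, []).append(k)
    result = []
    for rec, ws, we in triples:
        idx = by_rec.get(rec)
        if not idx:
            result.append(np.empty(0, dtype=np.int64))
            continue
        idx = np.asarray(idx, dtype=np.int64)
        ps = np.array([proms[k].start for k in idx])
        pe = np.array([proms[k].end for k in idx])
        hit = (ps <= we) & (pe >= ws)
        result.append(idx[hit])
    return result


def genes_in_windows(proms: list[PromoterInterval], windows) -> set[str]:
    """Symbols of genes whose promoter intersects >= 1 window (>= 1 shared base).

    A gene counts once no matter how many windows or transcripts hit.
    """
    hits = _overlap_matrix(proms, windows)
    syms = set()
    for arr in hits:
        for k in arr:
            syms.add(proms[k].symbol)
    return syms


# ---------------------------------------------------------------------------
# Monte-Carlo nulls
# ---------------------------------------------------------------------------

def _iter_rng(seed: int, iteration: int) -> np.random.Generator:
    """Independent, order-insensitive per-iteration generator."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(iteration)]))


@dataclass(frozen=True)
class MonteCarloResult:
    """Outcome of a randomization test.

    ``p`` is f/iterations, or the floor 1/iterations when no random draw
    reached the observed count (then ``p_is_floor`` is set and the text form
    reads "< 1/iterations").
    """

    observed: int
    expected: float
    f: int
    iterations: int
    seed: int

    @property
    def p(self) -> float:
        return (self.f if self.f > 0 else 1) / self.iterations

    @property
    def p_is_floor(self) -> bool:
        return self.f == 0

    @property
    def p_text(self) -> str:
        return f"<{1.0 / self.iterations:g}" if self.p_is_floor else f"{self.p:g}"

    @property
    def fold(self) -> float:
        return self.observed / self.expected if self.expected > 0 else float("inf")


def mc_gene_null(
    proms: list[PromoterInterval],
    observed: int,
    n: int,
    candidate_windows,
    iterations: int,
    seed: int,
) -> MonteCarloResult:
    """Gene count expected when n windows are drawn at random.

    Each iteration draws n distinct windows uniformly from the candidate
    (defined) window positions and counts the distinct genes whose promoters
    they hit.  E is the mean count; f the number of iterations reaching the
    observed count.
    """
    triples = _window_triples(candidate_windows)
    K = len(triples)
    if n < 1 or iterations < 1:
        raise ValueError("n and iterations must be >= 1")
    if n > K:
        raise ValueError(f"cannot draw {n} distinct windows from {K} available")
    win_gene_syms = []
    sym_index = {p.symbol: i for i, p in enumerate(proms)}
    sym_ids = np.array([sym_index[p.symbol] for p in proms])
    for arr in _overlap_matrix(proms, triples):
        win_gene_syms.append(np.unique(sym_ids[arr]))
    total = 0.0
    f = 0
    for it in range(iterations):
        rng = _iter_rng(seed, it)
        chosen = rng.choice(K, size=n, replace=False)
        parts = [win_gene_syms[c] for c in chosen]
        count = np.unique(np.concatenate(parts)).size if parts else 0
        total += count
        if count >= observed:
            f += 1
    return MonteCarloResult(
        observed=observed, expected=total / iterations, f=f,
        iterations=iterations, seed=seed,
    )


def annotate_windows(
    profile,
    min_cm: float,
    proms: list[PromoterInterval],
    iterations: int,
    seed: int,
):
    """Full annotate step: qualifying windows, their genes, and the MC null.

    Returns (qualifying windows DataFrame, observed gene symbols,
    MonteCarloResult).  Random windows are drawn from all defined windows of
    the profile.
    """
    defined = profile.defined()
    qualifying = defined[defined["cm"] >= min_cm]
    n = len(qualifying)
    if n == 0:
        logger.warning("no windows reach Cm >= %g", min_cm)
        return qualifying, set(), None
    observed = genes_in_windows(proms, qualifying)
    mc = mc_gene_null(proms, len(observed), n, defined, iterations, seed)
    return qualifying, observed, mc


# ---------------------------------------------------------------------------
# GO enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentResult:
    """Per-category enrichment: genome count C, observed O, expected E, fold, p."""

    category: str
    name: str
    C: int
    O: int
    E: float
    f: int
    iterations: int
    n_tested: int

    @property
    def fold(self) -> float:
        return self.O / self.E if self.E > 0 else float("inf")

    @property
    def p(self) -> float:
        return (self.f if self.f > 0 else 1) / self.iterations

    @property
    def p_is_floor(self) -> bool:
        return self.f == 0

    @property
    def p_text(self) -> str:
        return f"<{1.0 / self.iterations:g}" if self.p_is_floor else f"{self.p:g}"

    @property
    def p_bonferroni(self) -> float:
        return min(1.0, self.p * self.n_tested)


def go_enrichment(
    genes_observed: set[str],
    mapping: GoMapping,
    universe: list[str] | None = None,
    iterations: int = 10_000,
    seed: int = 0,
    min_members: int = 10,
) -> list[EnrichmentResult]:
    """Test GO biological-process categories for enrichment in observed genes.

    The gene universe defaults to all genes carrying >= 1 BP annotation.
    Only categories with >= ``min_members`` genes in the universe are tested.
    Each Monte-Carlo iteration resamples a gene set of the observed size
    (observed genes restricted to the universe) uniformly without replacement
    and records per-category counts; p-values are f/iterations with the
    1/iterations floor, Bonferroni-corrected over the tested categories.
    Results are sorted by fold enrichment, descending.
    """
    if universe is None:
        universe = mapping.annotated_genes()
    universe = sorted(set(universe))
    obs = sorted(set(genes_observed) & set(universe))
    if not obs:
        logger.warning("no observed genes fall in the annotated universe")
        return []
    uni_index = {g: i for i, g in enumerate(universe)}
    cats = sorted({c for g in universe for c in mapping.gene_to_go.get(g, ())})
    members = {c: [] for c in cats}
    for g in universe:
        for c in mapping.gene_to_go.get(g, ()):
            members[c].append(uni_index[g])
    tested = [c for c in cats if len(members[c]) >= min_members]
    if not tested:
        logger.warning("no category has >= %d members in the universe", min_members)
        return []
    M = np.zeros((len(universe), len(tested)), dtype=bool)
    for j, c in enumerate(tested):
        M[members[c], j] = True
    obs_idx = np.array([uni_index[g] for g in obs])
    O = M[obs_idx].sum(axis=0)
    nU, size = len(universe), len(obs)
    E_sum = np.zeros(len(tested))
    f = np.zeros(len(tested), dtype=np.int64)
    for it in range(iterations):
        rng = _iter_rng(seed, it)
        idx = rng.choice(nU, size=size, replace=False)
        counts = M[idx].sum(axis=0)
        E_sum += counts
        f += counts >= O
    results = [
        EnrichmentResult(
            category=c,
            name=mapping.terms.get(c, ("", ""))[0],
            C=len(members[c]),
            O=int(O[j]),
            E=float(E_sum[j] / iterations),
            f=int(f[j]),
            iterations=iterations,
            n_tested=len(tested),
        )
        for j, c in enumerate(tested)
    ]
    results.sort(key=lambda r: (-r.fold, r.p, r.category))
    return results


def enrichment_to_tsv(results: list[EnrichmentResult], path: str | Path) -> None:
    """Write enrichment results: #, process, C, O, E, O/E, p (floor as '<1/i')."""
    with open(path, "w") as fh:
        fh.write("#\tprocess\tid\tC\tO\tE\tO/E\tp\tp_bonferroni\n")
        for k, r in enumerate(results, start=1):
            fold = "inf" if not np.isfinite(r.fold) else f"{r.fold:.1f}"
            fh.write(
                f"{k}\t{r.name}\t{r.category}\t{r.C}\t{r.O}\t{r.E:.2f}\t"
                f"{fold}\t{r.p_text}\t{r.p_bonferroni:g}\n"
            )
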