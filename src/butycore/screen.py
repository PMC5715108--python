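"""Genotyping genomes for butyrate pathways from annotation tables.

Input is a table of gene hits (genome, taxon bin, gene symbol, locus
ordinal, model-similarity score, reference flag), the product of a
profile-HMM screen.  The screening rules applied here are:

1. Per gene symbol, a low-score cutoff is placed at the dominant score
   drop at or below the lowest-scoring reference sequence; everything
   below is discarded.
2. Within each genome, paralogous extra copies of a gene that are not
   syntenic with other genes of the same pathway (within 10 locus
   ordinals) are dropped when a higher-scoring syntenic copy exists.
3. etfA/etfB are only trusted when syntenic with bcd (the bifurcating
   butyryl-CoA dehydrogenase complex).
4. A pathway is called present when at most one core gene is missing.
   For the acetyl-CoA pathway, thl is never a criterion (alternative
   routes form acetoacetyl-CoA), and a genome missing one of the other
   core genes must carry a terminal enzyme (but or buk).
5. Ac-positive genomes are classified by terminal enzyme: but, buk,
   both, or "alternative" (neither).

Housekeeping genes are screened without drop detection (their sequences
are unique); copy numbers are recorded.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .pathways import (
    HOUSEKEEPING_GENES,
    PATHWAY_IDS,
    PATHWAYS,
    PathwayDefinition,
    get_pathway,
    pathways_of_gene,
)

#: Max locus-ordinal separation for two genes to be considered syntenic.
SYNTENY_WINDOW = 10

HIT_COLUMNS = ["genome_id", "taxon_bin", "gene_symbol", "locus_index", "score", "is_reference"]


@dataclass(frozen=True)
class GeneHit:
    """One screened gene hit in a genome."""

    genome_id: str
    gene_symbol: str
    locus_index: int
    score: float
    is_reference: bool = False
    taxon_bin: str = "unassigned"
    contig: str = "c0"

    def __post_init__(self) -> None:
        if self.locus_index < 0:
            raise ValueError("locus_index must be >= 0")
        if not np.isfinite(self.score):
            raise ValueError("score must be finite")


@dataclass
class GenomePathwayProfile:
    """Pathway genotype of one genome."""

    genome_id: str
    taxon_bin: str
    presence: dict[str, bool]
    expected_genes: dict[str, frozenset[str]]
    terminal_class: str | None = None  # only for Ac-positive genomes
    housekeeping_copies: dict[str, int] = field(default_factory=dict)


class ScreenError(Exception):
    """Configuration or state error in the genome screen."""


def detect_score_cutoff(
    scores: Iterable[float],
    is_reference: Iterable[bool],
    *,
    gap_factor: float = 2.0,
    window: float = 0.5,
    min_drop: float = 0.25,
) -> float:
    """Low-score cutoff for one gene: the dominant score drop below the
    lowest-scoring reference.

    The sorted score list is scanned for consecutive gaps whose upper
    score lies at or below the lowest reference score (and within
    ``window`` x that score).  A gap counts as an "obvious drop" when it
    both dominates the local gap structure (>= ``gap_factor`` x the
    median consecutive gap) and is large on the score scale itself
    (>= ``min_drop`` x the lowest reference score) — random scatter of
    genuine hits produces an outlier gap relative to the median, but
    not one comparable to the scores themselves.  The cutoff sits at
    the upper score of the dominant drop; with no qualifying drop it
    falls back to the lowest reference score.  Hits scoring below the
    returned cutoff are to be discarded.
    """
    scores = np.asarray(list(scores), dtype=float)
    refmask = np.asarray(list(is_reference), dtype=bool)
    if scores.size == 0 or not refmask.any():
        raise ScreenError("score-cutoff detection requires at least one reference hit")
    low_ref = scores[refmask].min()
    order = np.sort(scores)[::-1]
    floor = window * low_ref
    gaps: list[tuple[float, float]] = []  # (gap size, upper score)
    for hi, lo in zip(order[:-1], order[1:]):
        if lo < hi and hi <= low_ref and hi >= floor:
            gaps.append((hi - lo, hi))
    if not gaps:
        return low_ref
    sizes = np.array([g for g, _ in gaps])
    best_gap, best_upper = max(gaps)
    med = float(np.median(sizes))
    dominant = best_gap > 0 and (med == 0 or best_gap >= gap_factor * med)
    if dominant and best_gap >= min_drop * low_ref:
        return best_upper
    return low_ref


def apply_score_cutoffs(hits: pd.DataFrame, *, gap_factor: float = 2.0, window: float = 0.5) -> pd.DataFrame:
    """Apply per-gene score cutoffs across all genomes.

    Housekeeping genes are kept wholesale (no drop detection).  Pathway
    genes with no reference hit anywhere raise :class:`ScreenError`.
    """
    kept = []
    for gene, sub in hits.groupby("gene_symbol", sort=False):
        if gene in HOUSEKEEPING_GENES:
            kept.append(sub)
            continue
        cutoff = detect_score_cutoff(
            sub["score"], sub["is_reference"], gap_factor=gap_factor, window=window
        )
        kept.append(sub[sub["score"] >= cutoff])
    return pd.concat(kept, ignore_index=True) if kept else hits.iloc[0:0]


def _syntenic_partners(row, genome_hits: pd.DataFrame) -> bool:
    """Is this hit within the synteny window of another gene of one of
    its pathways (same contig, different gene symbol)?"""
    pids = set(pathways_of_gene(row.gene_symbol))
    for other in genome_hits.itertuples():
        if other.Index == row.Index or other.gene_symbol == row.gene_symbol:
            continue
        if getattr(other, "contig", "c0") != getattr(row, "contig", "c0"):
            continue
        if abs(other.locus_index - row.locus_index) <= SYNTENY_WINDOW:
            if pids & set(pathways_of_gene(other.gene_symbol)):
                return True
    return False


def filter_syntenic_paralogs(genome_hits: pd.DataFrame) -> pd.DataFrame:
    """Drop non-syntenic extra copies of multi-copy genes.

    A copy is syntenic when within :data:`SYNTENY_WINDOW` locus ordinals
    of another pathway gene of the same pathway on the same contig.
    Non-syntenic copies are dropped only when a syntenic copy of the same
    gene with a higher score exists; single copies are always kept.
    Idempotent.
    """
    if genome_hits.empty:
        return genome_hits
    if "contig" not in genome_hits.columns:
        genome_hits = genome_hits.assign(contig="c0")
    pathway_mask = ~genome_hits["gene_symbol"].isin(HOUSEKEEPING_GENES)
    pathway_hits = genome_hits[pathway_mask]
    syntenic = {
        row.Index: _syntenic_partners(row, pathway_hits)
        for row in pathway_hits.itertuples()
    }
    drop: set[int] = set()
    for gene, sub in pathway_hits.groupby("gene_symbol", sort=False):
        if len(sub) < 2:
            continue
        best_syntenic = max(
            (row.score for row in sub.itertuples() if syntenic[row.Index]),
            default=None,
        )
        if best_syntenic is None:
            continue
        for row in sub.itertuples():
            if not syntenic[row.Index] and row.score < best_syntenic:
                drop.add(row.Index)
    return genome_hits.drop(index=drop)


def validate_etfab(genome_hits: pd.DataFrame) -> pd.DataFrame:
    """Keep etfA/etfB only when syntenic with a retained bcd."""
    if genome_hits.empty:
        return genome_hits
    if "contig" not in genome_hits.columns:
        genome_hits = genome_hits.assign(contig="c0")
    bcd = genome_hits[genome_hits["gene_symbol"] == "bcd"]
    drop = []
    for row in genome_hits.itertuples():
        if row.gene_symbol not in ("etfA", "etfB"):
            continue
        ok = any(
            b.contig == row.contig and abs(b.locus_index - row.locus_index) <= SYNTENY_WINDOW
            for b in bcd.itertuples()
        )
        if not ok:
            drop.append(row.Index)
    return genome_hits.drop(index=drop)


def call_pathway(genes_present: Iterable[str], pathway: PathwayDefinition | str) -> tuple[bool, frozenset[str]]:
    """Genotype one pathway from the retained gene set of a genome.

    Present iff at most one counted core gene is missing; exempt genes
    (thl for Ac) never count as missing.  For the Ac pathway a genome
    missing a counted core gene must additionally carry a terminal
    enzyme (but or buk).  Returns ``(present, expected_gene_set)`` where
    the expected set is the pathway genes (core + terminal) the genome
    actually carries.
    """
    if isinstance(pathway, str):
        pathway = get_pathway(pathway)
    genes = set(genes_present)
    missing = [g for g in pathway.counted_core_genes if g not in genes]
    present = len(missing) <= 1
    if present and pathway.pathway_id == "Ac" and missing:
        present = bool(genes & set(pathway.terminal_genes))
    carried = frozenset(genes & set(pathway.core_genes + pathway.terminal_genes))
    return present, carried


def classify_terminal(genes_present: Iterable[str]) -> str:
    """Terminal-enzyme class of an Ac-positive genome."""
    genes = set(genes_present)
    has_but, has_buk = "but" in genes, "buk" in genes
    if has_but and has_buk:
        return "both"
    if has_but:
        return "but"
    if has_buk:
        return "buk"
    return "alternative"


def screen_genomes(
    hits: pd.DataFrame,
    *,
    gap_factor: float = 2.0,
    window: float = 0.5,
    apply_cutoffs: bool = True,
) -> list[GenomePathwayProfile]:
    """Full genotyping pipeline: score cutoffs, synteny filters, pathway
    calls and terminal classification, per genome.

    ``hits`` must have columns ``genome_id, taxon_bin, gene_symbol,
    locus_index, score, is_reference`` (optionally ``contig``).
    """
    missing_cols = set(HIT_COLUMNS) - set(hits.columns)
    if missing_cols:
        raise ScreenError(f"hit table missing columns: {sorted(missing_cols)}")
    if apply_cutoffs:
        hits = apply_score_cutoffs(hits, gap_factor=gap_factor, window=window)
    profiles = []
    for genome_id, sub in hits.groupby("genome_id", sort=False):
        sub = validate_etfab(filter_syntenic_paralogs(sub))
        genes = set(sub["gene_symbol"])
        taxon = sub["taxon_bin"].iloc[0] if len(sub) else "unassigned"
        presence, expected = {}, {}
        for pid in PATHWAY_IDS:
            presence[pid], expected[pid] = call_pathway(genes, pid)
        terminal = classify_terminal(genes) if presence["Ac"] else None
        hk = {
            g: int((sub["gene_symbol"] == g).sum()) for g in HOUSEKEEPING_GENES
        }
        profiles.append(
            GenomePathwayProfile(
                genome_id=str(genome_id),
                taxon_bin=str(taxon),
                presence=presence,
                expected_genes=expected,
                terminal_class=terminal,
                housekeeping_copies=hk,
            )
        )
    return profiles


def summarize_database(profiles: Iterable[GenomePathwayProfile]) -> pd.DataFrame:
    """Per-taxon pathway and terminal-class prevalence table."""
    profiles = list(profiles)
    if not profiles:
        raise ScreenError("summarize_database requires at least one profile")
    rows = []
    for p in profiles:
        row = {"genome_id": p.genome_id, "taxon_bin": p.taxon_bin}
        for pid in PATHWAY_IDS:
            row[pid] = p.presence[pid]
        for cls in ("but", "buk", "both", "alternative"):
            row[f"terminal_{cls}"] = p.terminal_class == cls
        rows.append(row)
    df = pd.DataFrame(rows)
    agg = df.drop(columns="genome_id").groupby("taxon_bin").mean()
    agg["n_genomes"] = df.groupby("taxon_bin").size()
    return agg.reset_index()


def profiles_to_frame(profiles: Iterable[GenomePathwayProfile]) -> pd.DataFrame:
    """Serialize profiles to a flat table (one row per genome)."""
    rows = []
    for p in profiles:
        row: dict = {"genome_id": p.genome_id, "taxon_bin": p.taxon_bin,
                     "terminal_class": p.terminal_class or ""}
        for pid in PATHWAY_IDS:
            row[f"present_{pid}"] = p.presence[pid]
            row[f"genes_{pid}"] = ",".join(sorted(p.expected_genes[pid]))
        rows.append(row)
    return pd.DataFrame(rows)


class TaxonProfileSet:
    """Per-taxon expected gene sets and terminal classes, aggregated from
    genome profiles.

    For each (taxon, pathway): the pathway is attributed to the taxon if
    any genome of the taxon carries it; ``carried_genes`` is the union of
    genes over those genomes (used for quantification) and
    ``required_genes`` their intersection (used for sample-level
    detection — genes absent from some reference genomes of the taxon
    are not demanded in samples).
    """

    def __init__(self, profiles: Iterable[GenomePathwayProfile]):
        self.carried: dict[tuple[str, str], frozenset[str]] = {}
        self.required: dict[tuple[str, str], frozenset[str]] = {}
        self.terminal_class: dict[str, str] = {}
        by_taxon: dict[str, list[GenomePathwayProfile]] = {}
        for p in profiles:
            by_taxon.setdefault(p.taxon_bin, []).append(p)
        for taxon, plist in by_taxon.items():
            for pid in PATHWAY_IDS:
                positives = [p for p in plist if p.presence[pid]]
                if not positives:
                    continue
                union = frozenset().union(*(p.expected_genes[pid] for p in positives))
                inter = frozenset.intersection(*(p.expected_genes[pid] for p in positives))
                self.carried[(taxon, pid)] = union
                self.required[(taxon, pid)] = inter
            classes = [p.terminal_class for p in plist if p.terminal_class]
            if classes:
                # majority class; ties resolved toward 'both'
                vals, counts = np.unique(classes, return_counts=True)
                winners = set(vals[counts == counts.max()])
                self.terminal_class[taxon] = "both" if len(winners) > 1 else winners.pop()

    def taxa_with(self, pathway_id: str) -> list[str]:
        return sorted(t for (t, pid) in self.carried if pid == pathway_id)

    def to_json(self) -> str:
        return json.dumps(
            {
                "carried": {f"{t}|{p}": sorted(v) for (t, p), v in self.carried.items()},
                "required": {f"{t}|{p}": sorted(v) for (t, p), v in self.required.items()},
                "terminal_class": self.terminal_class,
            },
            indent=2,
            sort_keys=True,
        )
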