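"""Quantification: from per-entry read counts to community abundances.

Raw read counts per catalogue entry are turned into abundances expressed
as percentages of total bacteria:

* reads on decoy entries are discarded,
* counts are pooled per (taxon bin, gene symbol) and divided by the
  median reference length of the gene (gene-length correction),
* the mean of the three housekeeping-gene totals (rplB, recA, pyrG) is
  the denominator — housekeeping genes are single-copy and universal, so
  their mean abundance proxies total bacterial abundance,
* pathway abundance = aggregate of the pathway's quantification genes
  (mean; median for the 4-aminobutyrate pathway) / denominator x 100,
* a taxon is present for a pathway when every required gene (the genes
  its reference genomes carry, minus the global exemptions gctA, atoA,
  atoD, kal) has at least ``min_reads`` raw reads; in low-depth
  metatranscriptome mode one missing gene is tolerated,
* taxon abundance = median over the taxon's pathway genes / denominator
  x 100,
* Ac-pathway taxa are grouped by terminal enzyme (taxa carrying both
  but and buk are split proportionally to the two genes' counts) and by
  taxonomic family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .catalogue import GeneCatalogue
from .pathways import (
    DETECTION_EXEMPT_GENES,
    FAMILY_GROUPS,
    HOUSEKEEPING_GENES,
    PATHWAY_IDS,
    PATHWAYS,
    PathwayDefinition,
    get_pathway,
)
from .screen import TaxonProfileSet


class QuantifyError(Exception):
    pass


@dataclass
class SampleCounts:
    """Raw read counts of one sample against the gene catalogue."""

    sample_id: str
    counts: dict[str, int]  # catalogue seq_id -> raw read count
    dataset_id: str = "ds0"
    subject_id: str = "s0"
    timepoint: int = 0
    group: str = ""
    data_mode: str = "metagenome"  # or "metatranscriptome_lowdepth"

    def __post_init__(self) -> None:
        for sid, c in self.counts.items():
            if c < 0 or int(c) != c:
                raise QuantifyError(f"count for {sid!r} must be a nonnegative integer")
        if self.data_mode not in ("metagenome", "metatranscriptome_lowdepth"):
            raise QuantifyError(f"unknown data_mode {self.data_mode!r}")

    def total(self) -> int:
        return int(sum(self.counts.values()))


@dataclass
class AbundanceProfile:
    """Pathway/taxon/enzyme-group/family abundances of one sample, as
    percentages of total bacteria."""

    sample_id: str
    pathway_abundance: dict[str, float]
    taxon_table: pd.DataFrame  # taxon_bin, pathway, present, abundance
    enzyme_groups: dict[str, float]
    family_groups: dict[str, float]
    richness: dict[str, int]
    taxon_linkage: dict[str, float]
    denominator: float = float("nan")
    metadata: dict = field(default_factory=dict)

    def taxon_abundances(self, pathway_id: str) -> dict[str, float]:
        sub = self.taxon_table[
            (self.taxon_table["pathway"] == pathway_id) & self.taxon_table["present"]
        ]
        return dict(zip(sub["taxon_bin"], sub["abundance"]))

    def to_long_frame(self) -> pd.DataFrame:
        df = self.taxon_table.copy()
        df.insert(0, "sample_id", self.sample_id)
        return df


# ---------------------------------------------------------------------------
# read mapping (toy stand-in for a real mapper)

def map_reads_naive(
    reads: Mapping[str, str], catalogue: GeneCatalogue, *, k: int = 31
) -> tuple[SampleCounts, int]:
    """Assign each read to the catalogue entry sharing its longest exact
    substring match of length >= k.

    Ties go to the entry first seen in catalogue order.  Returns the
    counts and the number of unassigned reads.  A toy mapper for
    error-free synthetic reads; not a Bowtie2 substitute.
    """
    if len(catalogue) == 0:
        raise QuantifyError("cannot map against an empty catalogue")
    index: dict[str, list[tuple[int, str, int]]] = {}
    for order, (sid, entry) in enumerate(catalogue.entries.items()):
        seq = entry.sequence
        for pos in range(len(seq) - k + 1):
            index.setdefault(seq[pos : pos + k], []).append((order, sid, pos))
    counts: dict[str, int] = {}
    unassigned = 0
    for read in reads.values():
        if len(read) < k:
            unassigned += 1
            continue
        # run-length of consecutive matching k-mers per (entry, diagonal)
        runs: dict[tuple[int, str, int], int] = {}
        for rpos in range(len(read) - k + 1):
            for order, sid, epos in index.get(read[rpos : rpos + k], ()):
                key = (order, sid, epos - rpos)
                runs[key] = runs.get(key, 0) + 1
        if not runs:
            unassigned += 1
            continue
        best = max(runs.items(), key=lambda kv: (kv[1], -kv[0][0]))
        sid = best[0][1]
        counts[sid] = counts.get(sid, 0) + 1
    return SampleCounts(sample_id="mapped", counts=counts), unassigned


# ---------------------------------------------------------------------------
# normalization steps

def filter_decoys(counts: SampleCounts, catalogue: GeneCatalogue) -> tuple[SampleCounts, int]:
    """Remove counts on decoy entries; returns (filtered, removed total)."""
    decoys = catalogue.decoy_ids()
    kept = {sid: c for sid, c in counts.counts.items() if sid not in decoys}
    removed = counts.total() - sum(kept.values())
    out = SampleCounts(
        sample_id=counts.sample_id, counts=kept, dataset_id=counts.dataset_id,
        subject_id=counts.subject_id, timepoint=counts.timepoint,
        group=counts.group, data_mode=counts.data_mode,
    )
    return out, int(removed)


def pool_counts(counts: SampleCounts, catalogue: GeneCatalogue) -> pd.DataFrame:
    """Raw counts pooled per (taxon_bin, gene_symbol)."""
    rows = []
    for sid, c in counts.counts.items():
        if sid not in catalogue:
            raise QuantifyError(f"count entry {sid!r} not in catalogue")
        e = catalogue[sid]
        rows.append((e.taxon_bin, e.gene_symbol, c))
    if not rows:
        return pd.DataFrame(columns=["taxon_bin", "gene_symbol", "raw"])
    df = pd.DataFrame(rows, columns=["taxon_bin", "gene_symbol", "raw"])
    return df.groupby(["taxon_bin", "gene_symbol"], as_index=False)["raw"].sum()


def length_correct(pooled: pd.DataFrame, catalogue: GeneCatalogue) -> pd.DataFrame:
    """Divide pooled raw counts by the median reference length of the gene."""
    out = pooled.copy()
    out["corrected"] = [
        raw / catalogue.median_length(gene)
        for gene, raw in zip(out["gene_symbol"], out["raw"])
    ]
    return out


def housekeeping_denominator(corrected: pd.DataFrame) -> float:
    """Mean of the three housekeeping genes' corrected totals.

    A housekeeping gene with no reads contributes 0 (with a warning);
    all three at zero flag the sample unquantifiable.
    """
    totals = []
    for gene in HOUSEKEEPING_GENES:
        sub = corrected[corrected["gene_symbol"] == gene]
        tot = float(sub["corrected"].sum())
        if tot == 0:
            warnings.warn(f"housekeeping gene {gene} undetected; contributes 0",
                          stacklevel=2)
        totals.append(tot)
    if all(t == 0 for t in totals):
        raise QuantifyError("all housekeeping genes undetected: sample unquantifiable")
    return float(np.mean(totals))


def pathway_abundance(
    corrected: pd.DataFrame, pathway: PathwayDefinition | str, denominator: float
) -> float:
    """Pathway abundance as % of total bacteria.

    Aggregate (mean, or median for 4A) of the pathway's quantification
    genes' corrected totals, over the housekeeping denominator, x100.
    Genes with no reads enter the aggregate as 0.
    """
    if isinstance(pathway, str):
        pathway = get_pathway(pathway)
    if denominator <= 0:
        raise QuantifyError("denominator must be positive")
    per_gene = []
    for gene in pathway.quant_genes:
        sub = corrected[corrected["gene_symbol"] == gene]
        per_gene.append(float(sub["corrected"].sum()))
    if not per_gene or all(v == 0 for v in per_gene):
        return 0.0
    agg = np.median(per_gene) if pathway.quant_aggregation == "median" else np.mean(per_gene)
    return float(agg) / denominator * 100.0


def taxon_presence(
    taxon_raw: Mapping[str, int],
    required_genes: Iterable[str],
    *,
    data_mode: str = "metagenome",
    min_reads: int = 1,
) -> bool:
    """Is a taxon present for a pathway in this sample?

    ``required_genes`` are the genes the taxon's reference genomes carry;
    the globally exempt genes (gctA, atoA, atoD, kal) are removed before
    checking.  Metagenome mode requires every remaining gene at
    ``min_reads`` raw reads; low-depth metatranscriptome mode tolerates
    one missing gene.
    """
    required = [g for g in required_genes if g not in DETECTION_EXEMPT_GENES]
    if not required:
        return False
    n_missing = sum(1 for g in required if taxon_raw.get(g, 0) < min_reads)
    allowed = 1 if data_mode == "metatranscriptome_lowdepth" else 0
    return n_missing <= allowed


def taxon_abundance(
    taxon_corrected: Mapping[str, float],
    pathway_genes: Iterable[str],
    denominator: float,
) -> float:
    """Taxon abundance for a pathway: median of the taxon's
    length-corrected pathway-gene counts over the denominator, x100."""
    values = [float(taxon_corrected.get(g, 0.0)) for g in pathway_genes]
    if not values:
        return 0.0
    return float(np.median(values)) / denominator * 100.0


def enzyme_groups(
    taxon_abundances: Mapping[str, float],
    terminal_class: Mapping[str, str],
    terminal_counts: Mapping[str, Mapping[str, float]],
) -> dict[str, float]:
    """Group Ac-pathway taxon abundances by terminal enzyme.

    Taxa of class ``both`` are split between but and buk proportionally
    to their two terminal genes' (length-corrected) counts; a both-taxon
    with zero counts on both genes splits 50/50 (flagged by warning).
    The group sum equals the taxon-abundance sum exactly.
    """
    groups = {"but": 0.0, "buk": 0.0, "alternative": 0.0}
    for taxon, ab in taxon_abundances.items():
        cls = terminal_class.get(taxon, "alternative")
        if cls == "both":
            tc = terminal_counts.get(taxon, {})
            b, k = float(tc.get("but", 0.0)), float(tc.get("buk", 0.0))
            if b + k == 0:
                warnings.warn(
                    f"both-class taxon {taxon} has no but/buk reads; splitting 50/50",
                    stacklevel=2,
                )
                frac_but = 0.5
            else:
                frac_but = b / (b + k)
            groups["but"] += ab * frac_but
            groups["buk"] += ab * (1 - frac_but)
        elif cls in ("but", "buk"):
            groups[cls] += ab
        else:
            groups["alternative"] += ab
    return groups


def family_groups(
    taxon_abundances: Mapping[str, float], taxonomy: Mapping[str, str]
) -> dict[str, float]:
    """Sum Ac-pathway taxon abundances per taxonomic family; taxa not
    mapped to a named family group go to "others"."""
    groups = {f: 0.0 for f in FAMILY_GROUPS}
    for taxon, ab in taxon_abundances.items():
        fam = taxonomy.get(taxon, "others")
        if fam not in groups:
            fam = "others"
        groups[fam] += ab
    return groups


def taxon_linkage(
    corrected: pd.DataFrame,
    pathway: PathwayDefinition | str,
    present_taxa: Iterable[str],
) -> float:
    """% of the pathway's quantification-gene reads assigned to a
    present taxon (abfD excluded for the 4A pathway).  Returns NaN when
    the pathway has no reads."""
    if isinstance(pathway, str):
        pathway = get_pathway(pathway)
    genes = [g for g in pathway.quant_genes if g not in pathway.linkage_excluded_genes]
    sub = corrected[corrected["gene_symbol"].isin(genes)]
    total = float(sub["raw"].sum())
    if total == 0:
        return float("nan")
    linked = float(sub[sub["taxon_bin"].isin(set(present_taxa))]["raw"].sum())
    return linked / total * 100.0


# ---------------------------------------------------------------------------
# full-sample profiling

def profile_sample(
    counts: SampleCounts,
    catalogue: GeneCatalogue,
    profiles: TaxonProfileSet,
    *,
    taxonomy: Mapping[str, str] | None = None,
    min_reads: int = 1,
) -> AbundanceProfile:
    """Run the complete quantification chain for one sample."""
    taxonomy = taxonomy or {}
    counts, n_decoy = filter_decoys(counts, catalogue)
    pooled = pool_counts(counts, catalogue)
    corrected = length_correct(pooled, catalogue)
    denom = housekeeping_denominator(corrected)

    pw_abundance = {
        pid: pathway_abundance(corrected, pid, denom) for pid in PATHWAY_IDS
    }

    raw_by_taxon: dict[str, dict[str, float]] = {}
    cor_by_taxon: dict[str, dict[str, float]] = {}
    for row in corrected.itertuples():
        raw_by_taxon.setdefault(row.taxon_bin, {})[row.gene_symbol] = row.raw
        cor_by_taxon.setdefault(row.taxon_bin, {})[row.gene_symbol] = row.corrected

    taxon_rows = []
    present_by_pathway: dict[str, list[str]] = {pid: [] for pid in PATHWAY_IDS}
    for (taxon, pid), required in sorted(profiles.required.items()):
        present = taxon_presence(
            raw_by_taxon.get(taxon, {}), required,
            data_mode=counts.data_mode, min_reads=min_reads,
        )
        carried = profiles.carried[(taxon, pid)]
        pdef = get_pathway(pid)
        quantifiable = [g for g in carried if g in pdef.quant_genes]
        ab = (
            taxon_abundance(cor_by_taxon.get(taxon, {}), quantifiable, denom)
            if present and quantifiable
            else 0.0
        )
        if present:
            present_by_pathway[pid].append(taxon)
        taxon_rows.append(
            {"taxon_bin": taxon, "pathway": pid, "present": present, "abundance": ab}
        )
    taxon_table = pd.DataFrame(
        taxon_rows, columns=["taxon_bin", "pathway", "present", "abundance"]
    )

    ac_ab = {
        r["taxon_bin"]: r["abundance"]
        for r in taxon_rows
        if r["pathway"] == "Ac" and r["present"]
    }
    terminal_counts = {
        t: {g: cor_by_taxon.get(t, {}).get(g, 0.0) for g in ("but", "buk")}
        for t in ac_ab
    }
    enzymes = enzyme_groups(ac_ab, profiles.terminal_class, terminal_counts)
    families = family_groups(ac_ab, taxonomy)
    richness = {pid: len(present_by_pathway[pid]) for pid in PATHWAY_IDS}
    linkage = {
        pid: taxon_linkage(corrected, pid, present_by_pathway[pid])
        for pid in PATHWAY_IDS
    }
    return AbundanceProfile(
        sample_id=counts.sample_id,
        pathway_abundance=pw_abundance,
        taxon_table=taxon_table,
        enzyme_groups=enzymes,
        family_groups=families,
        richness=richness,
        taxon_linkage=linkage,
        denominator=denom,
        metadata={
            "dataset_id": counts.dataset_id,
            "subject_id": counts.subject_id,
            "timepoint": counts.timepoint,
            "group": counts.group,
            "decoy_reads_removed": n_decoy,
        },
    )


def profiles_to_table(profiles: Iterable[AbundanceProfile]) -> pd.DataFrame:
    """Long-format abundance table over samples (one row per
    sample x taxon x pathway, plus pathway totals as taxon '_total')."""
    frames = []
    for p in profiles:
        df = p.to_long_frame()
        meta = p.metadata
        totals = pd.DataFrame(
            {
                "sample_id": p.sample_id,
                "taxon_bin": "_total",
                "pathway": list(p.pathway_abundance),
                "present": True,
                "abundance": list(p.pathway_abundance.values()),
            }
        )
        df = pd.concat([df, totals], ignore_index=True)
        for key in ("dataset_id", "subject_id", "timepoint", "group"):
            df[key] = meta.get(key, "")
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
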