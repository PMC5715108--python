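"""Synthetic data with known ground truth for the whole pipeline.

Generates every input the pipeline consumes: genome annotation tables
for the genotyping stage, nucleotide gene sequences for catalogue
construction, communities of taxa with defined pathway gene complements,
multinomial read counts (expected reads proportional to taxon abundance
x gene length), error-free reads for the toy mapper, longitudinal
designs with controllable direction-concordance of taxon changes, and
case/control designs with planted pathway-level effects.  Ground truth
is returned (and serialized) next to every generated artifact so that
parameter-recovery tests can close the loop.

The count model is multinomial across all (taxon, gene) cells at a
configured depth — the simplest model consistent with proportional
sampling; optional gamma overdispersion approximates negative-binomial
noise.  Sequences mutate under a uniform substitution model with no
indels, so nucleotide identity is exactly 1 - Hamming/length.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalogue import CatalogueEntry, GeneCatalogue
from .pathways import (
    HOUSEKEEPING_GENES,
    PATHWAY_IDS,
    PATHWAYS,
    TERMINAL_CLASSES,
)
from .quantify import SampleCounts

ALPHABET = np.array(list("ACGT"))

#: Default nucleotide gene lengths (nt).  Round numbers in the range
#: typical for the genes involved; kal is the short outlier of the
#: lysine pathway.
DEFAULT_GENE_LENGTHS: dict[str, int] = {
    "thl": 1180, "bhbd": 850, "cro": 780, "bcd": 1140, "etfA": 1010,
    "etfB": 780, "but": 1340, "buk": 1070,
    "gctA": 980, "gctB": 880, "hgCoAdA": 1230, "hgCoAdB": 1140,
    "hgCoAdC": 800, "gcdA": 1760, "gcdB": 1150,
    "abfH": 1120, "abfD": 1470, "4hbt": 1330,
    "kamA": 1250, "kamD": 1550, "kamE": 810, "kdd": 1040, "kce": 830,
    "kal": 300, "atoA": 650, "atoD": 660,
    "rplB": 830, "recA": 1060, "pyrG": 1650,
}

#: Default terminal-class frequencies for Ac-pathway taxa, matching the
#: healthy-cohort composition (but-dominant, few buk, some both/alt).
DEFAULT_TERMINAL_PROBS: dict[str, float] = {
    "but": 0.6, "buk": 0.15, "both": 0.15, "alternative": 0.10,
}

DEFAULT_FAMILY_PROBS: dict[str, float] = {
    "Lachnospiraceae": 0.45, "Ruminococcaceae": 0.35,
    "Porphyromonadaceae": 0.1, "others": 0.1,
}


class SynthError(ValueError):
    pass


# ---------------------------------------------------------------------------
# community specification

@dataclass(frozen=True)
class TaxonSpec:
    """One taxon of a synthetic community."""

    taxon_id: str
    family: str
    abundance: float
    pathways: tuple[str, ...]
    genes: frozenset[str]  # pathway genes carried (core + terminal)
    gene_lengths: Mapping[str, int] = field(default_factory=lambda: DEFAULT_GENE_LENGTHS)

    @property
    def terminal_class(self) -> str:
        has_but, has_buk = "but" in self.genes, "buk" in self.genes
        if has_but and has_buk:
            return "both"
        if has_but:
            return "but"
        if has_buk:
            return "buk"
        return "alternative"


@dataclass
class CommunitySpec:
    """A community: taxa with abundances summing to 1 (the background
    fraction carries only housekeeping genes)."""

    taxa: list[TaxonSpec]
    background_fraction: float = 0.0
    housekeeping_copies: int = 1

    def __post_init__(self) -> None:
        total = sum(t.abundance for t in self.taxa) + self.background_fraction
        if abs(total - 1.0) > 1e-9:
            raise SynthError(f"abundances + background must sum to 1 (got {total})")
        for t in self.taxa:
            for g in t.genes | set(HOUSEKEEPING_GENES):
                if t.gene_lengths.get(g, 0) < 150:
                    raise SynthError(f"gene length for {g} of {t.taxon_id} must be >= 150 nt")

    def true_pathway_abundance(self, pathway_id: str) -> float:
        """Ground-truth pathway abundance, % of total bacteria."""
        return 100.0 * sum(t.abundance for t in self.taxa if pathway_id in t.pathways)

    def taxonomy(self) -> dict[str, str]:
        return {t.taxon_id: t.family for t in self.taxa}

    def terminal_classes(self) -> dict[str, str]:
        return {t.taxon_id: t.terminal_class for t in self.taxa if "Ac" in t.pathways}

    def with_abundances(self, abundances: Sequence[float],
                        background: float | None = None) -> "CommunitySpec":
        bg = self.background_fraction if background is None else background
        taxa = [dataclasses.replace(t, abundance=a) for t, a in zip(self.taxa, abundances)]
        return CommunitySpec(taxa, bg, self.housekeeping_copies)

    def truth_frame(self) -> pd.DataFrame:
        rows = [
            {
                "taxon_id": t.taxon_id, "family": t.family,
                "abundance": t.abundance,
                "pathways": ",".join(t.pathways),
                "terminal_class": t.terminal_class,
            }
            for t in self.taxa
        ]
        rows.append({"taxon_id": "_background", "family": "", "abundance":
                     self.background_fraction, "pathways": "", "terminal_class": ""})
        return pd.DataFrame(rows)


@dataclass
class SimulationConfig:
    """Depth/design parameters for count simulation."""

    depth: int = 100_000
    seed: int = 0
    n_samples: int = 1
    design: str = "cross_sectional"
    dispersion: float | None = None  # gamma CV for NB-like overdispersion

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise SynthError("depth must be >= 1")
        if self.design not in ("cross_sectional", "longitudinal", "case_control"):
            raise SynthError(f"unknown design {self.design!r}")


def default_genes(pathways: Iterable[str], terminal_class: str = "both") -> frozenset[str]:
    """Full gene complement for a set of pathways and an Ac terminal class."""
    genes: set[str] = set()
    for pid in pathways:
        p = PATHWAYS[pid]
        genes |= set(p.core_genes)
        if pid == "Ac":
            if terminal_class == "but":
                genes.add("but")
            elif terminal_class == "buk":
                genes.add("buk")
            elif terminal_class == "both":
                genes |= {"but", "buk"}
        else:
            genes |= set(p.terminal_genes)
    return frozenset(genes)


def make_community(
    n_taxa: int = 20,
    *,
    background_fraction: float = 0.70,
    protein_pathway_probs: Mapping[str, float] | None = None,
    terminal_probs: Mapping[str, float] | None = None,
    family_probs: Mapping[str, float] | None = None,
    seed: int = 0,
) -> CommunitySpec:
    """A realistic butyrate-producing community.

    Every taxon carries the acetyl-CoA pathway (terminal class sampled
    from ``terminal_probs``); protein-fed pathways are added per taxon
    with the given probabilities.  Abundances of the producer taxa are
    lognormal, normalized to 1 - background_fraction; the background
    fraction carries only housekeeping genes.
    """
    if n_taxa < 1:
        raise SynthError("n_taxa must be >= 1")
    rng = np.random.default_rng(seed)
    pp = dict(protein_pathway_probs or {"Gl": 0.15, "4A": 0.12, "Ly": 0.20})
    tp = dict(terminal_probs or DEFAULT_TERMINAL_PROBS)
    fp = dict(family_probs or DEFAULT_FAMILY_PROBS)
    weights = rng.lognormal(mean=0.0, sigma=1.0, size=n_taxa)
    weights = weights / weights.sum() * (1.0 - background_fraction)
    taxa = []
    for i in range(n_taxa):
        pids = ["Ac"] + [p for p in ("Gl", "4A", "Ly") if rng.random() < pp[p]]
        cls = rng.choice(list(tp), p=np.array(list(tp.values())) / sum(tp.values()))
        fam = rng.choice(list(fp), p=np.array(list(fp.values())) / sum(fp.values()))
        taxa.append(
            TaxonSpec(
                taxon_id=f"t{i:03d}", family=str(fam), abundance=float(weights[i]),
                pathways=tuple(pids), genes=default_genes(pids, str(cls)),
            )
        )
    return CommunitySpec(taxa, background_fraction=background_fraction)


# ---------------------------------------------------------------------------
# genome annotation tables

def make_reference_genomes(
    n_taxa: int,
    pathway_prevalence: Mapping[str, float] | None = None,
    seed: int = 0,
    *,
    terminal_probs: Mapping[str, float] | None = None,
    true_score_band: tuple[float, float] = (80.0, 120.0),
    noise_score_band: tuple[float, float] = (10.0, 35.0),
    noise_rate: float = 0.0,
    reference_fraction: float = 0.3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic genome annotation tables with known pathway truth.

    One genome per taxon.  Pathways are present per genome with the
    given prevalence (default 1.0 for all four); present pathways carry
    their full gene roster with scores in ``true_score_band``, laid out
    syntenically (contiguous locus ordinals).  With ``noise_rate`` > 0,
    spurious low-score paralog hits in ``noise_score_band`` are added
    for random genes, to be removed by score-cutoff detection.  Per gene
    at least one hit is flagged as reference.

    Returns ``(hits, truth)``: the annotation table (genome_id,
    taxon_bin, gene_symbol, locus_index, score, is_reference, contig)
    and the truth table (genome_id, pathway, present, terminal_class).
    """
    if n_taxa < 1:
        raise SynthError("n_taxa must be >= 1")
    prevalence = {pid: 1.0 for pid in PATHWAY_IDS}
    prevalence.update(pathway_prevalence or {})
    for pid, v in prevalence.items():
        if not 0.0 <= v <= 1.0:
            raise SynthError(f"prevalence for {pid} must be in [0, 1]")
    tp = dict(terminal_probs or DEFAULT_TERMINAL_PROBS)
    rng = np.random.default_rng(seed)
    rows, truth_rows = [], []
    for i in range(n_taxa):
        gid, taxon = f"g{i:03d}", f"t{i:03d}"
        present = {pid: bool(rng.random() < prevalence[pid]) for pid in PATHWAY_IDS}
        cls = str(rng.choice(list(tp), p=np.array(list(tp.values())) / sum(tp.values())))
        genes = default_genes([p for p in PATHWAY_IDS if present[p]],
                              cls if present["Ac"] else "alternative")
        locus = 0
        for pid in PATHWAY_IDS:
            if not present[pid]:
                continue
            block = sorted(g for g in genes
                           if g in PATHWAYS[pid].core_genes + PATHWAYS[pid].terminal_genes)
            for g in block:
                rows.append((gid, taxon, g, locus, float(rng.uniform(*true_score_band)),
                             False, True))
                locus += 1
            locus += 30  # gap between pathway blocks
        for g in HOUSEKEEPING_GENES:
            rows.append((gid, taxon, g, locus, float(rng.uniform(*true_score_band)),
                         False, True))
            locus += 15
        if noise_rate > 0:
            for g in sorted(set(DEFAULT_GENE_LENGTHS) - set(HOUSEKEEPING_GENES)):
                if rng.random() < noise_rate:
                    rows.append((gid, taxon, g, locus + int(rng.integers(50, 500)),
                                 float(rng.uniform(*noise_score_band)), False, False))
        terminal = cls if present["Ac"] else ""
        for pid in PATHWAY_IDS:
            truth_rows.append(
                {"genome_id": gid, "taxon_bin": taxon, "pathway": pid,
                 "present": present[pid],
                 "terminal_class": terminal if pid == "Ac" else ""}
            )
    hits = pd.DataFrame(
        rows, columns=["genome_id", "taxon_bin", "gene_symbol", "locus_index",
                       "score", "is_reference", "_true"],
    )
    hits["contig"] = "c0"
    # flag references among the genuine hits: a random subset plus, per
    # gene, the lowest- and highest-scoring genuine hit — curated
    # reference sets span the full score range of real members
    ref_draw = rng.random(len(hits)) < reference_fraction
    hits["is_reference"] = ref_draw & hits["_true"]
    for gene, sub in hits[hits["_true"]].groupby("gene_symbol"):
        hits.loc[sub["score"].idxmax(), "is_reference"] = True
        hits.loc[sub["score"].idxmin(), "is_reference"] = True
    hits = hits.drop(columns="_true")
    truth = pd.DataFrame(truth_rows)
    return hits, truth


# ---------------------------------------------------------------------------
# gene sequences

def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length)


def _mutate_exact(rng: np.random.Generator, seq: np.ndarray, n_sites: int) -> np.ndarray:
    """Substitute exactly n_sites positions to a different base."""
    out = seq.copy()
    if n_sites == 0:
        return out
    pos = rng.choice(len(seq), size=n_sites, replace=False)
    out[pos] = (out[pos] + rng.integers(1, 4, size=n_sites)) % 4
    return out


def _to_str(seq: np.ndarray) -> str:
    return "".join(ALPHABET[seq])


def make_gene_sequences(
    genome_table: pd.DataFrame,
    within_cluster_divergence: float = 0.03,
    between_cluster_divergence: float = 0.10,
    seed: int = 0,
    *,
    gene_lengths: Mapping[str, int] | None = None,
    truncated: Iterable[tuple[str, str, float]] = (),
) -> tuple[dict[str, str], pd.DataFrame]:
    """Nucleotide sequences for every (gene symbol, taxon bin, genome).

    Per gene, a root sequence is drawn; per taxon an ancestor is derived
    from the root such that any two taxon ancestors differ at at least
    ``between_cluster_divergence`` of positions (verified, redrawn on
    violation).  Each member copies its taxon ancestor with exactly
    ``round(within/2 x L)`` substituted positions, so pairwise
    within-taxon divergence never exceeds ``within`` and cross-taxon
    divergence never falls below ``between - within``.

    ``truncated`` entries ``(gene_symbol, taxon_bin, fraction)`` append
    one extra record truncated to that fraction of the gene length, for
    length-filter tests.

    Returns ``(sequences, meta)`` with meta columns seq_id, gene_symbol,
    taxon_bin, genome_id, truncated.
    """
    w, b = within_cluster_divergence, between_cluster_divergence
    if not (0 <= w < b <= 1):
        raise SynthError("need 0 <= within < between <= 1")
    lengths = dict(gene_lengths or DEFAULT_GENE_LENGTHS)
    rng = np.random.default_rng(seed)
    sequences: dict[str, str] = {}
    meta_rows = []
    for gene, sub in genome_table.groupby("gene_symbol", sort=True):
        L = lengths.get(gene)
        if L is None:
            raise SynthError(f"no length for gene {gene!r}")
        root = _random_seq(rng, L)
        min_between = int(np.ceil(b * L))
        taxa = sorted(sub["taxon_bin"].unique())
        ancestors: dict[str, np.ndarray] = {}
        for taxon in taxa:
            for _ in range(200):
                cand = _mutate_exact(rng, root, min_between)
                if all(int((cand != a).sum()) >= min_between for a in ancestors.values()):
                    ancestors[taxon] = cand
                    break
            else:  # pragma: no cover - essentially unreachable
                raise SynthError("could not separate taxon ancestors")
        n_within = int(round(w / 2 * L))
        for row in sub.itertuples():
            member = _mutate_exact(rng, ancestors[row.taxon_bin], n_within)
            sid = f"{gene}|{row.taxon_bin}|{row.genome_id}"
            sequences[sid] = _to_str(member)
            meta_rows.append((sid, gene, row.taxon_bin, row.genome_id, False))
    for gene, taxon, fraction in truncated:
        L = lengths[gene]
        src = next((s for (s, g, t, _, tr) in meta_rows if g == gene and t == taxon and not tr), None)
        if src is None:
            raise SynthError(f"no member of ({gene}, {taxon}) to truncate")
        sid = f"{src}|trunc"
        sequences[sid] = sequences[src][: int(fraction * L)]
        meta_rows.append((sid, gene, taxon, "truncated", True))
    meta = pd.DataFrame(
        meta_rows, columns=["seq_id", "gene_symbol", "taxon_bin", "genome_id", "truncated"]
    )
    return sequences, meta


def reference_catalogue(
    community: CommunitySpec, seed: int = 0, *, decoy_taxa: int = 0
) -> GeneCatalogue:
    """Reference catalogue matching a community: one entry per
    (taxon, gene) plus housekeeping entries for the background bin and
    optional decoy entries from non-producer lineages."""
    rng = np.random.default_rng(seed)
    entries = []
    for t in community.taxa:
        for g in sorted(t.genes | set(HOUSEKEEPING_GENES)):
            seq = _to_str(_random_seq(rng, t.gene_lengths[g]))
            entries.append(
                CatalogueEntry(
                    seq_id=f"{g}|{t.taxon_id}", sequence=seq, gene_symbol=g,
                    taxon_bin=t.taxon_id, source="reference",
                )
            )
    if community.background_fraction > 0:
        for g in HOUSEKEEPING_GENES:
            seq = _to_str(_random_seq(rng, DEFAULT_GENE_LENGTHS[g]))
            entries.append(
                CatalogueEntry(
                    seq_id=f"{g}|_background", sequence=seq, gene_symbol=g,
                    taxon_bin="_background", source="reference",
                )
            )
    for d in range(decoy_taxa):
        for g in ("thl", "buk", "bhbd"):
            seq = _to_str(_random_seq(rng, DEFAULT_GENE_LENGTHS[g]))
            entries.append(
                CatalogueEntry(
                    seq_id=f"{g}|decoy{d:02d}", sequence=seq, gene_symbol=g,
                    taxon_bin=f"decoy{d:02d}", source="reference", is_decoy=True,
                )
            )
    return GeneCatalogue(entries)


# ---------------------------------------------------------------------------
# count simulation

def _cell_weights(
    community: CommunitySpec, catalogue: GeneCatalogue
) -> tuple[list[str], np.ndarray]:
    """Catalogue entry ids and unnormalized expected-read weights
    (abundance x gene length x copies)."""
    ids, weights = [], []
    for t in community.taxa:
        for g in sorted(t.genes | set(HOUSEKEEPING_GENES)):
            sid = f"{g}|{t.taxon_id}"
            if sid not in catalogue:
                raise SynthError(f"community gene {sid!r} not resolvable in catalogue")
            copies = community.housekeeping_copies if g in HOUSEKEEPING_GENES else 1
            ids.append(sid)
            weights.append(t.abundance * catalogue[sid].length * copies)
    if community.background_fraction > 0:
        for g in HOUSEKEEPING_GENES:
            sid = f"{g}|_background"
            if sid not in catalogue:
                raise SynthError(f"background housekeeping {sid!r} not in catalogue")
            ids.append(sid)
            weights.append(
                community.background_fraction * catalogue[sid].length
                * community.housekeeping_copies
            )
    return ids, np.asarray(weights, dtype=float)


def simulate_counts(
    community: CommunitySpec,
    catalogue: GeneCatalogue,
    config: SimulationConfig,
    *,
    sample_prefix: str = "sample",
    **sample_meta,
) -> list[SampleCounts]:
    """Multinomial read counts at the configured depth.

    Expected reads for gene g of taxon t are proportional to
    abundance_t x length_g; housekeeping cells include the background
    fraction.  With ``config.dispersion`` set, cell weights are
    gamma-perturbed per sample (negative-binomial-like overdispersion).
    """
    ids, weights = _cell_weights(community, catalogue)
    rng = np.random.default_rng(config.seed)
    out = []
    for s in range(config.n_samples):
        w = weights
        if config.dispersion:
            cv2 = config.dispersion**2
            w = weights * rng.gamma(shape=1 / cv2, scale=cv2, size=len(weights))
        draws = rng.multinomial(config.depth, w / w.sum())
        counts = {sid: int(c) for sid, c in zip(ids, draws) if c > 0}
        out.append(
            SampleCounts(
                sample_id=f"{sample_prefix}{s:03d}", counts=counts, **sample_meta
            )
        )
    return out


def expected_pathway_se(
    community: CommunitySpec,
    catalogue: GeneCatalogue,
    pathway_id: str,
    depth: int,
) -> float:
    """Analytic (delta-method) standard error of the estimated pathway
    abundance under the multinomial count model, in percentage points.

    The estimator is a ratio of linear combinations of multinomial cell
    counts (mean of length-corrected quantification-gene totals over the
    mean housekeeping total); its sampling variance follows from the
    multinomial covariance.  For the median-aggregated 4A pathway this
    is the mean-aggregation approximation.
    """
    pdef = PATHWAYS[pathway_id]
    ids, w = _cell_weights(community, catalogue)
    p = w / w.sum()
    c_num = np.zeros(len(ids))
    c_den = np.zeros(len(ids))
    for i, sid in enumerate(ids):
        gene = catalogue[sid].gene_symbol
        if gene in pdef.quant_genes:
            c_num[i] = 1.0 / (len(pdef.quant_genes) * catalogue.median_length(gene))
        if gene in HOUSEKEEPING_GENES:
            c_den[i] = 1.0 / (len(HOUSEKEEPING_GENES) * catalogue.median_length(gene))
    mu_x, mu_y = c_num @ p, c_den @ p
    # Var(a'N) = n(sum a_i^2 p_i - (a'p)^2) for multinomial N
    var_x = ((c_num**2) @ p - mu_x**2) / depth
    var_y = ((c_den**2) @ p - mu_y**2) / depth
    cov = ((c_num * c_den) @ p - mu_x * mu_y) / depth
    ratio = mu_x / mu_y
    var = ratio**2 * (var_x / mu_x**2 + var_y / mu_y**2 - 2 * cov / (mu_x * mu_y))
    return 100.0 * float(np.sqrt(max(var, 0.0)))


def simulate_reads(
    catalogue: GeneCatalogue,
    community: CommunitySpec,
    read_length: int = 100,
    depth: int = 1000,
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Error-free reads drawn from catalogue entries with probability
    proportional to abundance x length; provenance recorded per read."""
    ids, weights = _cell_weights(community, catalogue)
    min_len = min(catalogue[sid].length for sid in ids)
    if read_length > min_len:
        raise SynthError(
            f"read_length {read_length} exceeds shortest entry length {min_len}"
        )
    rng = np.random.default_rng(seed)
    if depth == 0:
        return {}, pd.DataFrame(columns=["read_id", "seq_id", "start"])
    draws = rng.multinomial(depth, weights / weights.sum())
    reads, prov = {}, []
    r = 0
    for sid, n in zip(ids, draws):
        seq = catalogue[sid].sequence
        for _ in range(int(n)):
            start = int(rng.integers(0, len(seq) - read_length + 1))
            rid = f"read{r:06d}"
            reads[rid] = seq[start : start + read_length]
            prov.append((rid, sid, start))
            r += 1
    return reads, pd.DataFrame(prov, columns=["read_id", "seq_id", "start"])


# ---------------------------------------------------------------------------
# designs

def make_longitudinal(
    community: CommunitySpec,
    n_timepoints: int,
    concordance: float = 0.5,
    magnitude: float = 0.3,
    seed: int = 0,
) -> tuple[list[CommunitySpec], pd.DataFrame]:
    """Longitudinal series: baseline plus shifted later timepoints.

    At each later timepoint every taxon's abundance is multiplied by
    (1 + s x magnitude) with s = -1 with probability ``concordance``
    (else +1), clipped at 0 (flagged) and renormalized.  Ground-truth
    signed pre-renormalization changes are returned.
    """
    if not 0 <= concordance <= 1:
        raise SynthError("concordance must be in [0, 1]")
    rng = np.random.default_rng(seed)
    series = [community]
    truth_rows = []
    base = np.array([t.abundance for t in community.taxa])
    for tp in range(1, n_timepoints):
        signs = np.where(rng.random(len(base)) < concordance, -1.0, 1.0)
        shifted = base * (1 + signs * magnitude)
        clipped = shifted < 0
        shifted = np.clip(shifted, 0, None)
        total = shifted.sum() + community.background_fraction
        new_ab = shifted / total
        new_bg = community.background_fraction / total
        series.append(community.with_abundances(new_ab, new_bg))
        for t, s, cl in zip(community.taxa, signs, clipped):
            truth_rows.append(
                {"timepoint": tp, "taxon_id": t.taxon_id,
                 "signed_change": float(s * magnitude * t.abundance),
                 "decreased": bool(s < 0), "clipped": bool(cl)}
            )
    return series, pd.DataFrame(truth_rows)


def make_case_control(
    community: CommunitySpec,
    pathway_effect: float,
    n_per_group: int,
    seed: int = 0,
    *,
    pathway: str = "Ac",
    noise_sigma: float = 0.25,
) -> tuple[list[CommunitySpec], list[CommunitySpec], dict]:
    """Case/control communities with a planted pathway-level effect.

    Per sample, taxon abundances are jittered lognormally
    (``noise_sigma``); in cases, taxa carrying the target pathway are
    additionally scaled by (1 + effect); each sample is renormalized.
    Returns (controls, cases, truth) where truth records the intended
    relative difference in percent (before renormalization distortion).
    """
    if pathway_effect <= -1:
        raise SynthError("pathway_effect must be > -1")
    if n_per_group < 2:
        raise SynthError("n_per_group must be >= 2")
    rng = np.random.default_rng(seed)
    base = np.array([t.abundance for t in community.taxa])
    target = np.array([pathway in t.pathways for t in community.taxa])

    def jittered(scale: np.ndarray) -> CommunitySpec:
        ab = base * scale * np.exp(rng.normal(0, noise_sigma, len(base)))
        total = ab.sum() + community.background_fraction
        return community.with_abundances(ab / total, community.background_fraction / total)

    controls = [jittered(np.ones(len(base))) for _ in range(n_per_group)]
    case_scale = np.where(target, 1.0 + pathway_effect, 1.0)
    cases = [jittered(case_scale) for _ in range(n_per_group)]
    truth = {
        "pathway": pathway,
        "intended_relative_difference_pct": 100.0 * pathway_effect,
        "baseline_pathway_abundance_pct": community.true_pathway_abundance(pathway),
    }
    return controls, cases, truth


def make_correlated_taxa(
    n_datasets: int,
    n_samples: int,
    planted_pairs: Sequence[tuple[int, int]],
    rho: float = 0.7,
    seed: int = 0,
    *,
    n_taxa: int = 20,
    sigma: float = 1.0,
) -> list[pd.DataFrame]:
    """Per-dataset taxon abundance tables with planted rank correlations.

    Gaussian-copula lognormal abundances: planted pairs share latent
    Gaussian correlation r = 2 sin(pi rho / 6) so that their population
    Spearman correlation equals ``rho``; all other taxa are independent.
    """
    if not abs(rho) < 1:
        raise SynthError("|rho| must be < 1")
    for i, j in planted_pairs:
        if not (0 <= i < n_taxa and 0 <= j < n_taxa) or i == j:
            raise SynthError(f"invalid planted pair ({i}, {j})")
    r = 2 * np.sin(np.pi * rho / 6)
    cov = np.eye(n_taxa)
    for i, j in planted_pairs:
        cov[i, j] = cov[j, i] = r
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_datasets):
        z = rng.multivariate_normal(np.zeros(n_taxa), cov, size=n_samples,
                                    method="cholesky")
        table = pd.DataFrame(
            np.exp(sigma * z), columns=[f"t{i:03d}" for i in range(n_taxa)]
        )
        out.append(table)
    return out
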