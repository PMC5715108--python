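"""End-to-end pipeline orchestration and I/O validation.

A run goes: synthesize genomes and a community -> genotype genomes ->
build the taxon profile set -> build the reference catalogue ->
simulate counts -> quantify every sample -> write abundance tables and
provenance.  All stage seeds are explicit in the configuration; a fixed
configuration reproduces its outputs byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .catalogue import GeneCatalogue
from .quantify import SampleCounts, profile_sample, profiles_to_table
from .screen import TaxonProfileSet, profiles_to_frame, screen_genomes
from .synth import (
    CommunitySpec,
    SimulationConfig,
    make_community,
    make_reference_genomes,
    reference_catalogue,
    simulate_counts,
)

log = logging.getLogger("butycore")


@dataclass
class RunConfig:
    """Configuration of a full synthetic pipeline run.

    Threshold defaults follow the established workflow: 95% clustering
    identity, 80% annotation coverage, 75% but/buk identity, 70% length
    fraction, rho 0.4 / support 3 for networks, prevalence cores at
    0.25/0.5/0.7/0.9, FDR 0.05.
    """

    out_dir: str = "butycore_run"
    seed: int = 0
    n_taxa: int = 20
    n_samples: int = 10
    depth: int = 100_000
    background_fraction: float = 0.70
    design: str = "cross_sectional"
    min_reads: int = 1
    data_mode: str = "metagenome"
    # stated workflow constants
    cluster_identity: float = 0.95
    annotation_coverage: float = 0.80
    terminal_identity: float = 0.75
    length_fraction: float = 0.70
    rho_min: float = 0.4
    min_support: int = 3
    fdr_alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Run the full synthetic pipeline; returns the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("stage synth: %d taxa, %d samples, depth %d",
             config.n_taxa, config.n_samples, config.depth)
    hits, truth = make_reference_genomes(config.n_taxa, seed=config.seed)
    community = make_community(
        config.n_taxa, background_fraction=config.background_fraction,
        seed=config.seed + 1,
    )
    hits.to_csv(out / "genome_hits.tsv", sep="\t", index=False)
    truth.to_csv(out / "genome_truth.tsv", sep="\t", index=False)
    community.truth_frame().to_csv(out / "community_truth.tsv", sep="\t", index=False)

    log.info("stage genotype")
    genome_profiles = screen_genomes(hits)
    profiles_to_frame(genome_profiles).to_csv(out / "genome_profiles.tsv",
                                              sep="\t", index=False)
    # sample-level detection uses the community's actual gene complements
    profile_set = TaxonProfileSet(_community_profiles(community))
    (out / "taxon_profiles.json").write_text(profile_set.to_json())

    log.info("stage catalogue")
    catalogue = reference_catalogue(community, seed=config.seed + 2, decoy_taxa=1)
    catalogue.write_manifest(out / "catalogue_manifest.tsv")
    catalogue.write_fasta(out / "catalogue.fasta")

    log.info("stage counts")
    sim = SimulationConfig(depth=config.depth, seed=config.seed + 3,
                           n_samples=config.n_samples, design=config.design)
    counts = simulate_counts(community, catalogue, sim, data_mode=config.data_mode)
    counts_frame(counts).to_csv(out / "counts.tsv", sep="\t", index=False)

    log.info("stage quantify")
    abundance_profiles = [
        profile_sample(c, catalogue, profile_set,
                       taxonomy=community.taxonomy(), min_reads=config.min_reads)
        for c in counts
    ]
    profiles_to_table(abundance_profiles).to_csv(out / "abundances.tsv",
                                                 sep="\t", index=False)

    provenance = {
        "config": asdict(config),
        "config_digest": config.digest(),
        "version": __version__,
        "stage_seeds": {"genomes": config.seed, "community": config.seed + 1,
                        "catalogue": config.seed + 2, "counts": config.seed + 3},
        "records": {
            "genomes": int(config.n_taxa),
            "catalogue_entries": len(catalogue),
            "samples": len(counts),
            "decoy_reads_removed": int(
                sum(p.metadata["decoy_reads_removed"] for p in abundance_profiles)
            ),
        },
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))
    return out


def _community_profiles(community: CommunitySpec):
    """Genome-profile view of a community's ground-truth gene complements."""
    from .screen import GenomePathwayProfile, call_pathway, classify_terminal
    from .pathways import PATHWAY_IDS

    profiles = []
    for t in community.taxa:
        presence, expected = {}, {}
        for pid in PATHWAY_IDS:
            presence[pid], expected[pid] = call_pathway(t.genes, pid)
        profiles.append(
            GenomePathwayProfile(
                genome_id=t.taxon_id, taxon_bin=t.taxon_id,
                presence=presence, expected_genes=expected,
                terminal_class=classify_terminal(t.genes) if presence["Ac"] else None,
            )
        )
    return profiles


def counts_frame(counts: list[SampleCounts]) -> pd.DataFrame:
    rows = []
    for c in counts:
        for sid, n in sorted(c.counts.items()):
            rows.append((c.sample_id, c.dataset_id, c.subject_id, c.timepoint,
                         c.group, sid, n))
    return pd.DataFrame(
        rows, columns=["sample_id", "dataset_id", "subject_id", "timepoint",
                       "group", "seq_id", "count"],
    )


def counts_from_frame(df: pd.DataFrame, data_mode: str = "metagenome") -> list[SampleCounts]:
    def _str(value, default):
        return default if pd.isna(value) else str(value)

    out = []
    for sample_id, sub in df.groupby("sample_id", sort=True):
        first = sub.iloc[0]
        out.append(
            SampleCounts(
                sample_id=str(sample_id),
                counts={r.seq_id: int(r.count) for r in sub.itertuples()},
                dataset_id=_str(first.get("dataset_id"), "ds0"),
                subject_id=_str(first.get("subject_id"), "s0"),
                timepoint=int(first.get("timepoint", 0)),
                group=_str(first.get("group"), ""),
                data_mode=data_mode,
            )
        )
    return out


def validate_io(
    counts_path=None, catalogue_fasta=None, catalogue_manifest=None
) -> list[str]:
    """Validate pipeline inputs; returns a list of error strings (empty
    when everything is consistent).  Problems are reported, never
    silently repaired."""
    errors: list[str] = []
    manifest = None
    if catalogue_manifest is not None:
        manifest = pd.read_csv(catalogue_manifest, sep="\t")
        required = {"seq_id", "gene_symbol", "taxon_bin", "length", "source", "is_decoy"}
        missing = required - set(manifest.columns)
        if missing:
            errors.append(f"catalogue manifest missing columns: {sorted(missing)}")
            manifest = None
    if catalogue_fasta is not None:
        from Bio import SeqIO

        try:
            records = list(SeqIO.parse(str(catalogue_fasta), "fasta"))
        except Exception as exc:  # malformed FASTA
            errors.append(f"catalogue FASTA unreadable: {exc}")
            records = []
        if not records:
            errors.append("catalogue FASTA contains no records")
        if manifest is not None and records:
            fasta_ids = {r.id for r in records}
            for sid in manifest["seq_id"]:
                if sid not in fasta_ids:
                    errors.append(f"manifest entry {sid!r} missing from FASTA")
    if counts_path is not None:
        df = pd.read_csv(counts_path, sep="\t")
        required = {"sample_id", "seq_id", "count"}
        missing = required - set(df.columns)
        if missing:
            errors.append(f"count table missing columns: {sorted(missing)}")
        else:
            bad = df[(df["count"] < 0) | (df["count"] != df["count"].astype(int))]
            for sample_id, seq_id, cnt in zip(bad["sample_id"], bad["seq_id"], bad["count"]):
                errors.append(
                    f"non-integral or negative count {cnt!r} for {sample_id}/{seq_id}"
                )
            if manifest is not None:
                known = set(manifest["seq_id"])
                for sid in sorted(set(df["seq_id"]) - known):
                    errors.append(f"count entry {sid!r} not in catalogue manifest")
    return errors
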