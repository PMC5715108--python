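"""Butyrate-synthesis pathway definitions.

Four routes lead to butyrate in colonic bacteria: the carbohydrate-fed
acetyl-CoA pathway (``Ac``), and three protein-fed pathways — glutarate
(``Gl``), 4-aminobutyrate (``4A``) and lysine (``Ly``).  Each pathway is a
fixed roster of genes; the final step to butyrate is carried out by one of
several terminal enzymes (butyryl-CoA:acetate CoA transferase *but*,
butyrate kinase *buk*, butyryl-CoA:4-hydroxybutyrate CoA transferase
*4hbt*, butyryl-CoA:acetoacetate CoA transferase *atoA/atoD*).

This module is the single source of truth for:

* which genes form each pathway's core and terminal set,
* which genes are used for quantification (terminal genes and the shared
  bcd–etfAB complex are excluded; gcdB is excluded from Gl because it
  recruits false-positive reads; the 4A pathway is aggregated by median
  because abfD recruits disproportionately many reads),
* which genes are exempt from presence requirements (thl has alternative
  routes and is never a genotyping criterion for Ac; gctA, atoA, atoD and
  kal are not required for sample-level taxon detection),
* the three single-copy housekeeping genes (rplB, recA, pyrG) whose mean
  abundance proxies total bacterial abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

PATHWAY_IDS = ("Ac", "Gl", "4A", "Ly")

HOUSEKEEPING_GENES = ("rplB", "recA", "pyrG")

#: Genes of the electron-bifurcating butyryl-CoA dehydrogenase complex.
#: The complex takes part in every pathway, so it is never used for
#: quantification; etfA/etfB are only trusted when syntenic with bcd.
BCD_ETFAB = ("bcd", "etfA", "etfB")

#: Family groups reported for the Ac pathway community.
FAMILY_GROUPS = ("Lachnospiraceae", "Ruminococcaceae", "Porphyromonadaceae", "others")

#: Terminal-enzyme classes of Ac-pathway producers.
TERMINAL_CLASSES = ("but", "buk", "both", "alternative")


@dataclass(frozen=True)
class PathwayDefinition:
    """Gene roster and aggregation rules for one butyrate pathway.

    Parameters
    ----------
    pathway_id
        One of ``Ac``, ``Gl``, ``4A``, ``Ly``.
    core_genes
        Genes whose (near-complete) presence defines carriage of the
        pathway in a genome.
    terminal_genes
        Terminal-enzyme genes analysed separately from the core.
    quant_genes
        Genes whose length-corrected counts enter the pathway abundance.
    quant_aggregation
        ``"mean"`` or ``"median"`` over the quantification genes.
    presence_exempt_genes
        Genes never counted as missing when genotyping a genome.
    detection_exempt_genes
        Genes not required for sample-level taxon detection.
    """

    pathway_id: str
    core_genes: tuple[str, ...]
    terminal_genes: tuple[str, ...] = ()
    quant_genes: tuple[str, ...] = ()
    quant_aggregation: str = "mean"
    presence_exempt_genes: tuple[str, ...] = ()
    detection_exempt_genes: tuple[str, ...] = ()
    # genes excluded from the taxon-linkage denominator (abfD for 4A)
    linkage_excluded_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.pathway_id not in PATHWAY_IDS:
            raise ValueError(f"unknown pathway id {self.pathway_id!r}")
        if not set(self.quant_genes) <= set(self.core_genes):
            raise ValueError("quant_genes must be a subset of core_genes")
        if set(self.quant_genes) & set(self.terminal_genes + BCD_ETFAB):
            raise ValueError("terminal genes and bcd-etfAB are never quantified")
        if self.quant_aggregation not in ("mean", "median"):
            raise ValueError("quant_aggregation must be 'mean' or 'median'")

    @property
    def counted_core_genes(self) -> tuple[str, ...]:
        """Core genes that count toward the missing-gene tally."""
        return tuple(g for g in self.core_genes if g not in self.presence_exempt_genes)


AC = PathwayDefinition(
    pathway_id="Ac",
    core_genes=("thl", "bhbd", "cro", "bcd", "etfA", "etfB"),
    terminal_genes=("but", "buk"),
    quant_genes=("thl", "bhbd", "cro"),
    quant_aggregation="mean",
    presence_exempt_genes=("thl",),
)

GL = PathwayDefinition(
    pathway_id="Gl",
    core_genes=("gctA", "gctB", "hgCoAdA", "hgCoAdB", "hgCoAdC", "gcdA", "gcdB"),
    terminal_genes=(),
    # gcdB recruits many false positives and is excluded from quantification
    quant_genes=("gctA", "gctB", "hgCoAdA", "hgCoAdB", "hgCoAdC", "gcdA"),
    quant_aggregation="mean",
    detection_exempt_genes=("gctA",),
)

FOUR_A = PathwayDefinition(
    pathway_id="4A",
    core_genes=("abfH", "abfD"),
    terminal_genes=("4hbt",),
    quant_genes=("abfH", "abfD"),
    # abfD recruits proportionally many reads; the median damps it
    quant_aggregation="median",
    linkage_excluded_genes=("abfD",),
)

LY = PathwayDefinition(
    pathway_id="Ly",
    core_genes=("kamA", "kamD", "kamE", "kdd", "kce", "kal"),
    terminal_genes=("atoA", "atoD"),
    quant_genes=("kamA", "kamD", "kamE", "kdd", "kce", "kal"),
    quant_aggregation="mean",
    detection_exempt_genes=("atoA", "atoD", "kal"),
)

PATHWAYS: dict[str, PathwayDefinition] = {p.pathway_id: p for p in (AC, GL, FOUR_A, LY)}

#: All pathway gene symbols (core + terminal, all four pathways).
PATHWAY_GENES: tuple[str, ...] = tuple(
    dict.fromkeys(
        g for p in PATHWAYS.values() for g in p.core_genes + p.terminal_genes
    )
)

#: Full gene vocabulary: pathway genes plus housekeeping genes.
ALL_GENES: tuple[str, ...] = PATHWAY_GENES + HOUSEKEEPING_GENES

#: Genes globally exempt from sample-level taxon-detection requirements.
DETECTION_EXEMPT_GENES: frozenset[str] = frozenset(
    g for p in PATHWAYS.values() for g in p.detection_exempt_genes
)


def pathways_of_gene(gene: str) -> tuple[str, ...]:
    """Pathways a gene belongs to (bcd-etfAB belongs to all four)."""
    if gene in BCD_ETFAB:
        return PATHWAY_IDS
    out = []
    for pid, p in PATHWAYS.items():
        if gene in p.core_genes or gene in p.terminal_genes:
            out.append(pid)
    return tuple(out)


def get_pathway(pathway_id: str) -> PathwayDefinition:
    try:
        return PATHWAYS[pathway_id]
    except KeyError:
        raise KeyError(f"unknown pathway id {pathway_id!r}") from None
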