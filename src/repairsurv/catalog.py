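"""Gene-set catalogs: DNA repair pathways, proliferation signature, driver lists.

The repair catalog is an ordered mapping of the eight canonical repair
pathway codes to gene symbol lists:

    DRR   direct reversal repair
    BER   base excision repair
    NHEJ  non-homologous end-joining
    MMR   mismatch repair
    TLS   translesion synthesis
    DDS   DNA damage signaling
    HRR   homologous recombination repair
    NER   nucleotide excision repair

A symbol may appear in several raw pathway lists (polymerases especially);
after first-occurrence deduplication each symbol belongs to exactly one
pathway, and the packaged catalog holds 123 unique genes.  PCNA (itself a
proliferation marker) and TP53 (a near-universal driver) are excluded from
the survival gene pool, leaving 121 genes.

Symbols are matched case-insensitively after trimming; aliases are not
resolved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import FormatError

logger = logging.getLogger(__name__)

#: Canonical pathway codes, in catalog order (used for first-occurrence dedup).
PATHWAY_CODES = ("DRR", "BER", "NHEJ", "MMR", "TLS", "DDS", "HRR", "NER")

#: Genes removed from the survival pool for every cancer.
DEFAULT_ALWAYS_EXCLUDE = ("PCNA", "TP53")


def _norm(symbol: str) -> str:
    return symbol.strip().upper()


@dataclass
class PathwayCatalog:
    """Deduplicated pathway -> gene-list mapping with provenance.

    ``provenance`` records, per gene, the pathway of first occurrence and any
    duplicate listings that were dropped.
    """

    pathways: dict[str, list[str]]
    provenance: dict[str, dict] = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        """All catalog genes, pathway order then within-pathway order."""
        return [g for genes in self.pathways.values() for g in genes]

    def pathway_of(self, gene: str) -> str:
        g = _norm(gene)
        for code, genes in self.pathways.items():
            if g in genes:
                return code
        raise KeyError(f"gene {gene!r} not in catalog")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class MetageneGeneSet:
    """Proliferation (PCNA-correlated) signature used to build the metagene."""

    genes: list[str]
    source_threshold: str = "r>0.65 with PCNA across normal tissues"

    def __post_init__(self) -> None:
        self.genes = [_norm(g) for g in self.genes]
        if not self.genes:
            raise FormatError("metagene signature is empty")
        if len(set(self.genes)) != len(self.genes):
            raise FormatError("metagene signature has duplicate symbols")


@dataclass
class DriverGeneSet:
    """Per-cancer driver genes (top-20 consensus lists)."""

    cancer_code: str
    genes: list[str]
    excluded_for_ger: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes = [_norm(g) for g in self.genes]
        if len(set(self.genes)) != len(self.genes):
            raise FormatError(
                f"driver list for {self.cancer_code} has duplicate symbols"
            )

    def ger_genes(self) -> list[str]:
        excl = {_norm(g) for g in self.excluded_for_ger}
        return [g for g in self.genes if g not in excl]


@dataclass
class ExclusionRules:
    """Symbols removed from the survival gene pool."""

    always_exclude: tuple[str, ...] = DEFAULT_ALWAYS_EXCLUDE
    per_cancer_driver_overlap: Mapping[str, Sequence[str]] = field(
        default_factory=dict
    )


def _parse_geneset_file(path: str | Path) -> list[tuple[str, list[str]]]:
    """Parse a GMT (name, description, genes...) or two-column TSV
    (set, gene) file into ordered (set-name, genes) records."""
    path = Path(path)
    records: list[tuple[str, list[str]]] = []
    lines = [
        ln.rstrip("\n")
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise FormatError(f"{path}: empty gene-set file")
    if path.suffix.lower() == ".gmt":
        for ln in lines:
            parts = ln.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: GMT line with <3 fields: {ln[:60]}")
            records.append((parts[0].strip(), [_norm(g) for g in parts[2:] if g.strip()]))
        return records
    # two-column TSV, optional header
    order: list[str] = []
    by_set: dict[str, list[str]] = {}
    start = 1 if lines[0].lower().split("\t")[:2] in (
        ["pathway", "gene"], ["set", "gene"], ["name", "gene"]) else 0
    for ln in lines[start:]:
        parts = ln.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}: expected 2 columns, got {len(parts)}: {ln[:60]}")
        name, gene = parts[0].strip(), _norm(parts[1])
        if name not in by_set:
            order.append(name)
            by_set[name] = []
        by_set[name].append(gene)
    return [(name, by_set[name]) for name in order]


def deduplicate_first_occurrence(
    raw: Mapping[str, Iterable[str]] | Sequence[tuple[str, Iterable[str]]],
) -> PathwayCatalog:
    """Keep each symbol only in the first pathway where it occurs.

    Pathway order is the order given; dropped duplicate listings are recorded
    in provenance.  Idempotent.
    """
    items = raw.items() if isinstance(raw, Mapping) else raw
    pathways: dict[str, list[str]] = {}
    provenance: dict[str, dict] = {}
    for code, genes in items:
        kept: list[str] = []
        for g in genes:
            g = _norm(g)
            if g in provenance:
                provenance[g]["dropped"].append(code)
                logger.info("duplicate listing of %s in %s dropped (kept in %s)",
                            g, code, provenance[g]["first_pathway"])
            elif g in kept:
                provenance[g]["dropped"].append(code)
            else:
                kept.append(g)
                provenance[g] = {"first_pathway": code, "dropped": []}
        pathways[code] = kept
    return PathwayCatalog(pathways=pathways, provenance=provenance)


def load_pathway_catalog(path: str | Path) -> PathwayCatalog:
    """Load and deduplicate a repair-pathway catalog from GMT or TSV.

    Pathway codes must be drawn from the eight canonical codes; a code
    listed twice or an empty pathway is a format error.
    """
    records = _parse_geneset_file(path)
    seen: set[str] = set()
    for code, genes in records:
        if code not in PATHWAY_CODES:
            raise FormatError(f"unknown pathway code {code!r}; expected one of {PATHWAY_CODES}")
        if code in seen:
            raise FormatError(f"pathway code {code!r} listed twice")
        if not genes:
            raise FormatError(f"pathway {code!r} has no genes")
        seen.add(code)
    return deduplicate_first_occurrence(records)


def survival_gene_pool(
    catalog: PathwayCatalog,
    rules: ExclusionRules | None = None,
    cancer_code: str | None = None,
) -> list[str]:
    """Catalog genes minus exclusions, in stable catalog order.

    Exclusion symbols absent from the catalog are warned about, not fatal.
    """
    rules = rules or ExclusionRules()
    excluded = {_norm(g) for g in rules.always_exclude}
    if cancer_code is not None:
        excluded |= {
            _norm(g)
            for g in rules.per_cancer_driver_overlap.get(cancer_code, ())
        }
    catalog_genes = catalog.genes
    missing = excluded - set(catalog_genes)
    if missing:
        logger.warning("exclusion symbols not in catalog: %s", sorted(missing))
    return [g for g in catalog_genes if g not in excluded]


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("repairsurv.data").joinpath(name)


def load_packaged_catalog() -> PathwayCatalog:
    """The repair-pathway catalog bundled with the package (123 genes)."""
    with resources.as_file(_data_path("table1_pathways.tsv")) as p:
        return load_pathway_catalog(p)


def load_packaged_metagene_signature() -> MetageneGeneSet:
    """Bundled 131-symbol proliferation signature.

    The packaged symbols are SYNTHETIC placeholders (PCNASIG001..131) matching
    the names the synthetic cohort generator emits; supply your own GMT to
    analyse real data.
    """
    with resources.as_file(_data_path("synthetic_pcna_signature.gmt")) as p:
        records = _parse_geneset_file(p)
    return MetageneGeneSet(genes=records[0][1])


def load_metagene_signature(path: str | Path) -> MetageneGeneSet:
    records = _parse_geneset_file(path)
    return MetageneGeneSet(genes=records[0][1])


def load_driver_lists(path: str | Path) -> dict[str, DriverGeneSet]:
    """Per-cancer driver gene sets from a GMT file (one line per cancer)."""
    return {
        name: DriverGeneSet(cancer_code=name, genes=genes)
        for name, genes in _parse_geneset_file(path)
    }


def load_packaged_driver_lists() -> dict[str, DriverGeneSet]:
    """Bundled driver lists. SYNTHETIC placeholders (TP53 + DRV symbols)."""
    with resources.as_file(_data_path("synthetic_driver_lists.gmt")) as p:
        return load_driver_lists(p)


def load_cancer_manifest():
    """The 18-cancer manifest: code, name, stage availability."""
    import pandas as pd

    with resources.as_file(_data_path("cancer_manifest.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"has_stage": bool})
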