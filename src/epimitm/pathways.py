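"""Keyword-driven pathway, gene, and CpG preselection (the dimension-reduction
step of the meet-in-the-middle design).

Each outcome carries a keyword profile (e.g. the social-problems profile is
{children, brain, neuron, autism, social}).  A pathway is selected for an
outcome when any keyword occurs — case-insensitively, as a substring — in the
pathway's name, description, disease annotation, or reference titles.  The
member genes of the selected pathways, intersected with the genes annotated
on the array manifest, define the CpG universe that outcome is screened
against.  Substring (rather than whole-word) matching is the deliberate
convention: it is deterministic, order-free, and monotone in the keyword set.

Gene sets travel in GMT format with a sidecar metadata table for the
searchable text fields; the manifest maps CpG ids to chromosome, position and
gene symbol(s) (semicolon-separated when a CpG is annotated to several genes —
a CpG is selected if any of its genes is).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "Pathway",
    "PathwaySet",
    "KeywordProfile",
    "CpgUniverse",
    "match_keyword",
    "select_universe",
    "read_gmt",
    "write_gmt",
    "read_pathway_metadata",
    "write_pathway_metadata",
    "read_manifest",
    "write_manifest",
    "cpg_gene_map",
    "DEFAULT_KEYWORD_PROFILES",
]


@dataclass(frozen=True)
class Pathway:
    id: str
    genes: tuple[str, ...]
    name: str = ""
    description: str = ""
    disease: str = ""
    reference_titles: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"pathway {self.id!r} has an empty gene list")


@dataclass
class PathwaySet:
    """An ordered collection of pathways with unique ids."""

    pathways: list[Pathway]

    def __post_init__(self) -> None:
        ids = [p.id for p in self.pathways]
        if len(set(ids)) != len(ids):
            raise ValueError("pathway ids must be unique")

    def __iter__(self):
        return iter(self.pathways)

    def __len__(self) -> int:
        return len(self.pathways)

    def __getitem__(self, pid: str) -> Pathway:
        for p in self.pathways:
            if p.id == pid:
                return p
        raise KeyError(pid)


@dataclass(frozen=True)
class KeywordProfile:
    """The keyword set attached to one outcome."""

    outcome: str
    keywords: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.keywords:
            raise ValueError(f"empty keyword list for outcome {self.outcome!r}")
        object.__setattr__(
            self, "keywords", tuple(k.lower() for k in self.keywords)
        )


#: Published keyword profiles for the neurodevelopmental outcome battery:
#: full-scale IQ, CBCL internalizing/externalizing composites, CBCL social and
#: attention syndrome scales, and the DSM-oriented ADHD scale, each assessed
#: at two ages.  All profiles share {children, brain, neuron}; the remaining
#: keywords are outcome-specific.
DEFAULT_KEYWORD_PROFILES: dict[str, tuple[str, ...]] = {
    "iq_age5": ("children", "brain", "neuron", "intelligent", "intelligence", "iq"),
    "iq_age7": ("children", "brain", "neuron", "intelligent", "intelligence", "iq"),
    "cbcl_internal_age7": ("children", "brain", "neuron", "depressed", "depression", "depressive"),
    "cbcl_internal_age9": ("children", "brain", "neuron", "depressed", "depression", "depressive"),
    "cbcl_external_age7": ("children", "brain", "neuron", "aggression", "aggressive"),
    "cbcl_external_age9": ("children", "brain", "neuron", "aggression", "aggressive"),
    "cbcl_social_age7": ("children", "brain", "neuron", "autism", "social"),
    "cbcl_social_age9": ("children", "brain", "neuron", "autism", "social"),
    "cbcl_attention_age7": ("children", "brain", "neuron", "attention", "hyperactivity"),
    "cbcl_attention_age9": ("children", "brain", "neuron", "attention", "hyperactivity"),
    "dsm_adhd_age7": ("children", "brain", "neuron", "attention", "hyperactivity"),
    "dsm_adhd_age9": ("children", "brain", "neuron", "attention", "hyperactivity"),
}


@dataclass(frozen=True)
class CpgUniverse:
    """The reduced search space one outcome is screened against."""

    outcome: str
    pathway_ids: frozenset[str]
    genes: frozenset[str]
    annotated_genes: frozenset[str]
    cpg_ids: frozenset[str]

    def counts(self) -> dict[str, int]:
        """Pathway/gene/annotated-gene/CpG counts for the selection report."""
        return {
            "n_pathways": len(self.pathway_ids),
            "n_genes": len(self.genes),
            "n_annotated_genes": len(self.annotated_genes),
            "n_cpgs": len(self.cpg_ids),
        }


def match_keyword(pathway: Pathway, keyword: str) -> bool:
    """True iff ``keyword`` occurs (case-insensitive substring) in the
    pathway's name, description, disease, or any reference title."""
    if not keyword:
        raise ValueError("keyword must be non-empty")
    kw = keyword.lower()
    fields = (pathway.name, pathway.description, pathway.disease, *pathway.reference_titles)
    return any(kw in f.lower() for f in fields)


def cpg_gene_map(manifest: pd.DataFrame) -> dict[str, tuple[str, ...]]:
    """CpG id -> annotated gene symbols (splitting the semicolon dialect)."""
    out: dict[str, tuple[str, ...]] = {}
    for cpg, gene in manifest["gene"].items():
        if pd.isna(gene) or gene == "":
            out[cpg] = ()
        else:
            out[cpg] = tuple(g for g in str(gene).split(";") if g)
    return out


def select_universe(
    pathways: PathwaySet,
    profile: KeywordProfile,
    manifest: pd.DataFrame,
) -> CpgUniverse:
    """Map one outcome's keywords to pathways, genes, and CpGs.

    Selected pathways are the union over keywords of keyword matches; selected
    genes are all member genes of those pathways; annotated genes are the
    intersection with gene symbols present on the manifest; selected CpGs are
    every manifest CpG annotated to at least one selected gene.  A profile
    matching no pathway yields an empty universe with a warning — the outcome
    is then skipped downstream.
    """
    matched = [
        p for p in pathways if any(match_keyword(p, kw) for kw in profile.keywords)
    ]
    if not matched:
        warnings.warn(
            f"no pathway matched any keyword for outcome {profile.outcome!r}"
        )
        return CpgUniverse(profile.outcome, frozenset(), frozenset(), frozenset(), frozenset())
    genes = frozenset(g for p in matched for g in p.genes)
    gene_map = cpg_gene_map(manifest)
    manifest_genes = frozenset(g for gs in gene_map.values() for g in gs)
    annotated = genes & manifest_genes
    cpgs = frozenset(
        cpg for cpg, gs in gene_map.items() if any(g in genes for g in gs)
    )
    return CpgUniverse(
        outcome=profile.outcome,
        pathway_ids=frozenset(p.id for p in matched),
        genes=genes,
        annotated_genes=annotated,
        cpg_ids=cpgs,
    )


# ---------------------------------------------------------------------------
# file formats


def write_gmt(pathways: PathwaySet, path) -> None:
    """GMT: one pathway per line — id, description, then member genes."""
    with open(path, "w") as fh:
        for p in pathways:
            fh.write("\t".join([p.id, p.name or p.id, *p.genes]) + "\n")


def read_gmt(path) -> PathwaySet:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            out.append(Pathway(id=parts[0], name=parts[1], genes=tuple(parts[2:])))
    return PathwaySet(out)


def write_pathway_metadata(pathways: PathwaySet, path) -> None:
    """Sidecar table of the searchable text fields (reference titles pipe-joined)."""
    df = pd.DataFrame(
        {
            "pathway_id": [p.id for p in pathways],
            "name": [p.name for p in pathways],
            "description": [p.description for p in pathways],
            "disease": [p.disease for p in pathways],
            "reference_titles": ["|".join(p.reference_titles) for p in pathways],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_pathway_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return df.set_index("pathway_id")


def attach_metadata(gene_sets: PathwaySet, metadata: pd.DataFrame) -> PathwaySet:
    """Merge GMT gene memberships with the sidecar text metadata."""
    out = []
    for p in gene_sets:
        if p.id in metadata.index:
            row = metadata.loc[p.id]
            titles = tuple(t for t in str(row["reference_titles"]).split("|") if t)
            out.append(
                Pathway(
                    id=p.id,
                    genes=p.genes,
                    name=str(row["name"]),
                    description=str(row["description"]),
                    disease=str(row["disease"]),
                    reference_titles=titles,
                )
            )
        else:
            out.append(p)
    return PathwaySet(out)


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, sep="\t", index=True, index_label="cpg_id")


def read_manifest(path) -> pd.DataFrame:
    """Manifest TSV: cpg_id, chr, pos (1-based), gene (semicolon-joined)."""
    df = pd.read_csv(path, sep="\t", dtype={"chr": str, "gene": str})
    return df.set_index("cpg_id")
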