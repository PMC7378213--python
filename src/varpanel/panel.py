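"""Aggregation of per-document associations into gene panels.

The triplet table collects every (variant, gene, disease) association with
its per-document evidence; a disease's variant-driven gene panel is then
simply the set of genes carrying at least one variant associated with that
disease, each gene keeping the union of its supporting variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .association import AssociationResult, PairStatus, VariantGenePair
from .ner import VariantKey

__all__ = ["Triplet", "Panel", "aggregate_triplets", "build_panel", "rank_genes",
           "write_triplets_tsv", "write_panel_tsv"]


@dataclass
class Triplet:
    variant: VariantKey
    gene: str
    disease_id: str
    evidence: list[tuple[str, float]] = field(default_factory=list)

    @property
    def n_docs(self) -> int:
        return len({doc_id for doc_id, _ in self.evidence})


@dataclass
class Panel:
    disease_id: str
    genes: dict[str, set[VariantKey]] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.genes)

    @property
    def gene_symbols(self) -> list[str]:
        return sorted(self.genes)


def aggregate_triplets(
    associations_by_doc: Mapping[str, Sequence[AssociationResult]],
    pairs_by_doc: Mapping[str, Sequence[VariantGenePair]],
) -> list[Triplet]:
    """Merge per-document results into the global triplet table.

    A triplet exists for every document where a variant has both a RESOLVED
    gene pair and an assigned disease; the same (variant, gene, disease)
    from several documents merges into one triplet with the evidence list
    carrying each document's winning score.  Output is sorted by
    (disease, gene, variant) so aggregation is order-independent.
    """
    table: dict[tuple[str, str, str], Triplet] = {}
    for doc_id, assocs in associations_by_doc.items():
        resolved = {
            p.variant.canonical: p
            for p in pairs_by_doc.get(doc_id, ())
            if p.status is PairStatus.RESOLVED
        }
        for assoc in assocs:
            if assoc.assigned_disease is None:
                continue
            pair = resolved.get(assoc.variant.canonical)
            if pair is None:
                continue
            key = (assoc.assigned_disease, pair.gene, assoc.variant.canonical)
            if key not in table:
                table[key] = Triplet(
                    variant=assoc.variant,
                    gene=pair.gene,
                    disease_id=assoc.assigned_disease,
                )
            table[key].evidence.append((doc_id, assoc.score or 0.0))
    return [table[k] for k in sorted(table)]


def build_panel(triplets: Iterable[Triplet], disease_id: str) -> Panel:
    """Variant-driven gene panel for one disease.

    Genes with at least one triplet for the disease, each with the union of
    its variants.  An unknown disease yields an empty panel.
    """
    panel = Panel(disease_id=disease_id)
    for t in triplets:
        if t.disease_id == disease_id:
            panel.genes.setdefault(t.gene, set()).add(t.variant)
    return panel


def rank_genes(panel: Panel) -> list[tuple[str, int]]:
    """Genes ordered by distinct-variant count (desc), ties alphabetical."""
    return sorted(
        ((g, len(vs)) for g, vs in panel.genes.items()),
        key=lambda gv: (-gv[1], gv[0]),
    )


def write_triplets_tsv(triplets: Sequence[Triplet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("variant\tgene\tdisease\tn_docs\tdoc_ids\n")
        for t in triplets:
            docs = ";".join(sorted({d for d, _ in t.evidence}))
            fh.write(f"{t.variant.canonical}\t{t.gene}\t{t.disease_id}\t{t.n_docs}\t{docs}\n")


def write_panel_tsv(panel: Panel, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tn_variants\tvariants\n")
        for gene, n in rank_genes(panel):
            variants = ";".join(sorted(v.canonical for v in panel.genes[gene]))
            fh.write(f"{gene}\t{n}\t{variants}\n")
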