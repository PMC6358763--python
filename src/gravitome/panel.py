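"""Gene panel representation and probe-set selection.

The analysis is restricted to a curated panel of genes around HIF-1 signaling
(the published panel holds 176 genes: the KEGG hsa04066 pathway members plus
literature-curated interactors).  On each array platform, probe sets (or
transcript clusters, treated uniformly as probe sets) are selected for the
panel by matching gene symbol AND Entrez id under the *current* genome
annotation; where the array vendor's original annotation disagrees with the
current one, the current annotation alone governs inclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd


@dataclass(frozen=True)
class GenePanelEntry:
    gene_symbol: str
    entrez_id: int

    def __post_init__(self) -> None:
        if not self.gene_symbol or not str(self.gene_symbol).strip():
            raise ValueError("gene_symbol must be non-empty")
        if int(self.entrez_id) <= 0:
            raise ValueError("entrez_id must be a positive integer")


@dataclass(frozen=True)
class ProbeSetAnnotation:
    """One platform annotation row: array-era and current gene assignment."""

    probe_set_id: str
    platform_id: str
    array_symbol: str
    array_entrez: int | None
    current_symbol: str
    current_entrez: int | None


@dataclass(frozen=True)
class PanelSelection:
    platform_id: str
    selected: frozenset[str]
    per_gene: dict[str, list[str]]  # gene symbol -> sorted probe-set ids
    missing_genes: list[str]

    def __post_init__(self) -> None:
        n = sum(len(v) for v in self.per_gene.values())
        if n != len(self.selected):
            raise ValueError("per_gene does not partition the selected set")
        covered = {g for g, v in self.per_gene.items() if v}
        if covered & set(self.missing_genes):
            raise ValueError("missing_genes overlaps genes with probe sets")

    @property
    def n_genes_covered(self) -> int:
        return sum(1 for v in self.per_gene.values() if v)


def _norm_symbol(symbol: str) -> str:
    return str(symbol).strip().upper()


def _symbol_components(symbol: str) -> list[str]:
    # Multi-gene annotations like "NOS3; ATG9B" match on any component.
    return [s for s in (_norm_symbol(p) for p in str(symbol).split(";")) if s]


def validate_panel(panel: list[GenePanelEntry]) -> None:
    seen: set[int] = set()
    for entry in panel:
        if entry.entrez_id in seen:
            raise ValueError(f"duplicate entrez_id {entry.entrez_id} in panel")
        seen.add(entry.entrez_id)


def select_panel_probe_sets(
    panel: list[GenePanelEntry],
    annotations: list[ProbeSetAnnotation],
) -> PanelSelection:
    """Select platform probe sets matching the panel under current annotation.

    A probe set is selected iff its current (symbol, Entrez) pair matches a
    panel entry: symbols case-insensitively after whitespace trimming, with
    multi-gene annotations split on ';' and matched on any component, and the
    Entrez id agreeing exactly (Entrez disagreement vetoes a symbol match).
    The array-era annotation never influences the decision.  Panel genes with
    no selected probe set are reported in ``missing_genes``.
    """
    validate_panel(panel)
    platforms = {a.platform_id for a in annotations}
    if len(platforms) > 1:
        raise ValueError(f"annotations span multiple platforms: {sorted(platforms)}")
    platform_id = platforms.pop() if platforms else ""
    seen_ids: set[str] = set()
    for a in annotations:
        if a.probe_set_id in seen_ids:
            raise ValueError(f"duplicate probe_set_id {a.probe_set_id!r}")
        seen_ids.add(a.probe_set_id)

    by_entrez = {e.entrez_id: e for e in panel}
    per_gene: dict[str, list[str]] = {e.gene_symbol: [] for e in panel}
    selected: set[str] = set()
    for a in annotations:
        if a.current_entrez is None:
            continue
        entry = by_entrez.get(int(a.current_entrez))
        if entry is None:
            continue
        if _norm_symbol(entry.gene_symbol) in _symbol_components(a.current_symbol):
            selected.add(a.probe_set_id)
            per_gene[entry.gene_symbol].append(a.probe_set_id)
    per_gene = {g: sorted(v) for g, v in per_gene.items()}
    missing = sorted(g for g, v in per_gene.items() if not v)
    return PanelSelection(
        platform_id=platform_id,
        selected=frozenset(selected),
        per_gene=per_gene,
        missing_genes=missing,
    )


# -- TSV interfaces --------------------------------------------------------


def read_panel(path: str | Path) -> list[GenePanelEntry]:
    """Panel TSV with columns ``gene_symbol``, ``entrez_id``."""
    df = pd.read_csv(path, sep="\t")
    entries = []
    for row in df.itertuples():
        if pd.isna(row.entrez_id):
            raise ValueError(f"panel entry {row.gene_symbol!r} lacks an Entrez id")
        entries.append(GenePanelEntry(str(row.gene_symbol), int(row.entrez_id)))
    validate_panel(entries)
    return entries


def read_annotations(path: str | Path) -> list[ProbeSetAnnotation]:
    """Annotation TSV; empty strings in the Entrez columns mean absent."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"probe_set_id": str, "platform_id": str,
               "array_symbol": str, "current_symbol": str},
        keep_default_na=False,
    )
    out = []
    for row in df.itertuples():
        out.append(
            ProbeSetAnnotation(
                probe_set_id=row.probe_set_id,
                platform_id=row.platform_id,
                array_symbol=row.array_symbol,
                array_entrez=int(row.array_entrez) if str(row.array_entrez) != "" else None,
                current_symbol=row.current_symbol,
                current_entrez=int(row.current_entrez) if str(row.current_entrez) != "" else None,
            )
        )
    return out


def write_selection_report(
    selection: PanelSelection,
    panel: list[GenePanelEntry],
    tsv_path: str | Path,
    json_path: str | Path | None = None,
) -> dict:
    """Selection TSV (probe_set_id, gene_symbol, entrez_id) + JSON summary."""
    entrez_by_symbol = {e.gene_symbol: e.entrez_id for e in panel}
    rows = [
        {"probe_set_id": pid, "gene_symbol": gene, "entrez_id": entrez_by_symbol[gene]}
        for gene, pids in sorted(selection.per_gene.items())
        for pid in pids
    ]
    pd.DataFrame(rows, columns=["probe_set_id", "gene_symbol", "entrez_id"]).to_csv(
        tsv_path, sep="\t", index=False
    )
    summary = {
        "platform": selection.platform_id,
        "n_selected": len(selection.selected),
        "n_genes_covered": selection.n_genes_covered,
        "missing_genes": selection.missing_genes,
    }
    if json_path is not None:
        import json

        Path(json_path).write_text(json.dumps(summary, indent=2))
    return summary
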