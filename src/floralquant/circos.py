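"""Chord-diagram (Circos-style) data export of the gene→organ network.

The primary artifact here is the *data contract*: deterministic,
byte-stable CSV tables of sectors (genes, organs, configured gene
combinations) and weighted links (gene/combination → organ, weighted by
contribution sums), plus a self-contained R/circlize renderer script for
optional plotting.  Rendering fidelity is explicitly not guaranteed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .model import CombinationTable, ContributionResult, FloralModel, GradientResult

__all__ = ["CircosTables", "build_circos_tables", "write_renderer_files",
           "read_circos_tables"]

_FMT = "{:.6f}"  # fixed-point, 6 decimals, for byte-stable files


@dataclass(frozen=True)
class CircosTables:
    sectors: pd.DataFrame  # columns: name, kind, total, gradient
    links: pd.DataFrame    # columns: source, target, weight

    def organ_in_weight(self, organ: str) -> float:
        return float(self.links.loc[self.links["target"] == organ, "weight"].sum())


def build_circos_tables(
    model: FloralModel,
    contributions: ContributionResult,
    combinations: CombinationTable | None = None,
    gradient: GradientResult | None = None,
) -> CircosTables:
    """Sector and link records for chord plotting.

    One sector per organ (whorl order), per gene class (model order) and
    per combination row; links carry the contribution of each gene (or
    combination cell) into each organ it builds.  Organ sector totals are
    the incoming link-weight sums, so conservation holds by construction;
    gradient values, when given, are attached to organ sectors.
    """
    values = contributions.all_contributions
    links = []
    for g in model.gene_classes:
        for o in model.organs:
            if o.name in g.builds_organs and values.get(g.name, 0.0) > 0:
                links.append((g.name, o.name, values[g.name]))
    if combinations is not None:
        for label, row in combinations.rows.items():
            if set(row) != set(model.organ_names):
                raise ValueError(f"combination row {label!r} labels do not match model organs")
            for o in model.organs:
                if row[o.name] > 0:
                    links.append((label, o.name, row[o.name]))
    links_df = pd.DataFrame(links, columns=["source", "target", "weight"])

    if gradient is not None and set(gradient.values) != set(model.organ_names):
        raise ValueError("gradient labels do not match model organs")

    sectors = []
    for o in model.organs:
        sectors.append((
            o.name, "organ",
            float(links_df.loc[links_df["target"] == o.name, "weight"].sum()),
            float(gradient.values[o.name]) if gradient is not None else float("nan"),
        ))
    for g in model.gene_classes:
        sectors.append((
            g.name, "gene",
            float(links_df.loc[links_df["source"] == g.name, "weight"].sum()),
            float("nan"),
        ))
    if combinations is not None:
        for label in combinations.rows:
            sectors.append((
                label, "gene-combination",
                float(links_df.loc[links_df["source"] == label, "weight"].sum()),
                float("nan"),
            ))
    sectors_df = pd.DataFrame(sectors, columns=["name", "kind", "total", "gradient"])
    return CircosTables(sectors=sectors_df, links=links_df)


def _write_csv(df: pd.DataFrame, path: Path, float_cols: tuple[str, ...]) -> None:
    out = df.copy()
    for c in float_cols:
        out[c] = out[c].map(lambda v: _FMT.format(v) if pd.notna(v) else "")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        out.to_csv(fh, index=False, lineterminator="\n")


_R_SCRIPT = """\
#!/usr/bin/env Rscript
# Chord-diagram rendering of the exported sector/link tables (circlize).
# Usage: Rscript render_circos.R [directory] — reads sectors.csv/links.csv,
# writes circos.pdf alongside them.
suppressMessages(library(circlize))
args <- commandArgs(trailingOnly = TRUE)
dir <- if (length(args) >= 1) args[[1]] else "."
sectors <- read.csv(file.path(dir, "sectors.csv"), stringsAsFactors = FALSE)
links <- read.csv(file.path(dir, "links.csv"), stringsAsFactors = FALSE)
pdf(file.path(dir, "circos.pdf"))
circos.clear()
circos.par(gap.degree = 2)
grid.col <- setNames(rainbow(nrow(sectors)), sectors$name)
chordDiagram(links[, c("source", "target", "weight")],
             order = sectors$name, grid.col = grid.col,
             annotationTrack = c("name", "grid"))
meta <- paste("circlize", as.character(packageVersion("circlize")),
              "R", paste(R.version$major, R.version$minor, sep = "."))
title(sub = meta)
dev.off()
"""


def write_renderer_files(tables: CircosTables, directory: str | Path) -> list[Path]:
    """Write ``sectors.csv``, ``links.csv`` and ``render_circos.R``.

    Files are UTF-8, LF line endings, fixed column order, 6-decimal
    fixed-point weights — re-running on identical inputs is byte-identical.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sectors_path = directory / "sectors.csv"
    links_path = directory / "links.csv"
    script_path = directory / "render_circos.R"
    _write_csv(tables.sectors, sectors_path, ("total", "gradient"))
    _write_csv(tables.links, links_path, ("weight",))
    with open(script_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_R_SCRIPT)
    return [sectors_path, links_path, script_path]


def read_circos_tables(directory: str | Path) -> CircosTables:
    """Round-trip reader for :func:`write_renderer_files` output."""
    directory = Path(directory)
    sectors = pd.read_csv(directory / "sectors.csv")
    links = pd.read_csv(directory / "links.csv")
    if links.empty:
        links = pd.DataFrame(columns=["source", "target", "weight"])
    links["weight"] = links.get("weight", pd.Series(dtype=float)).astype(float)
    sectors["total"] = sectors["total"].astype(float)
    return CircosTables(sectors=sectors, links=links)
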