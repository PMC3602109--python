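"""End-to-end pipeline: matrix -> (BPA coding) -> search -> consensus ->
character optimization -> endemism, with all artifacts written to disk and
one machine-readable JSON summary."""
from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

from . import io as agio
from .bpa import TaxonCladogram, bpa_code
from .consensus import majority_consensus, optimize_characters
from .endemism import detect_endemism
from .geoprep import build_matrix, grid_quadrats, read_occurrences, assign_provinces
from .parsimony import SearchConfig, heuristic_search, tree_stats

log = logging.getLogger("areagram")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    # input: either a ready-made matrix, or occurrences + OGU mode
    matrix_path: str | None = None
    matrix_dialect: str = "csv"
    occurrences_path: str | None = None
    ogu_mode: str = "quadrat"  # "quadrat" | "province"
    cell_deg: float = 5.0
    anchor: tuple[float, float] = (0.0, 0.0)
    province_source: str | None = None
    taxon_tree_path: str | None = None  # enables BPA coding
    # analysis
    replicates: int = 100
    max_trees: int = 10000
    ratchet: bool = False
    consensus_cutoff: float = 0.5
    endemism_threshold: int = 2
    # run
    output_dir: str = "areagram_out"
    seed: int = 0
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["anchor"] = list(self.anchor)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    def validate(self) -> None:
        if self.matrix_path is None and self.occurrences_path is None:
            raise ValueError("either matrix_path or occurrences_path is required")
        for p in (self.matrix_path, self.occurrences_path,
                  self.taxon_tree_path, self.province_source):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured analysis; returns the summary dict."""
    config.validate()
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, config.verbosity.upper(), logging.INFO),
        format="%(name)s %(levelname)s: %(message)s",
    )
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        if config.matrix_path:
            log.info("loading matrix from %s (%s)", config.matrix_path, config.matrix_dialect)
            matrix = agio.read_matrix(config.matrix_path, config.matrix_dialect)
        else:
            log.info("reading occurrences from %s", config.occurrences_path)
            records = read_occurrences(config.occurrences_path)
            taxa = sorted({r.taxon for r in records})
            if config.ogu_mode == "quadrat":
                log.info("gridding at %s deg, anchor %s", config.cell_deg, config.anchor)
                ogus, assignment = grid_quadrats(records, config.cell_deg, tuple(config.anchor))
                matrix = build_matrix(records, assignment, taxa, ogus=ogus)
            elif config.ogu_mode == "province":
                assignment, unassigned = assign_provinces(records, config.province_source)
                if unassigned:
                    log.warning("unassigned records: %s", unassigned)
                    assignment = {i: a for i, a in assignment.items()}
                matrix = build_matrix(records, assignment, taxa)
            else:
                raise ValueError(f"unknown ogu_mode {config.ogu_mode!r}")
            matrix = matrix.drop_empty_areas()
        agio.write_matrix(matrix, out / "matrix.csv", "csv")

        coded = matrix
        if config.taxon_tree_path:
            stage = "bpa_code"
            log.info("BPA coding with %s", config.taxon_tree_path)
            tree = TaxonCladogram.from_newick(Path(config.taxon_tree_path).read_text())
            coded = bpa_code(tree, matrix)
            agio.write_matrix(coded, out / "matrix_bpa.csv", "csv")

        stage = "search"
        sc = SearchConfig(
            replicates=config.replicates,
            max_trees=config.max_trees,
            seed=config.seed,
            ratchet=config.ratchet,
        )
        log.info("heuristic search: %d replicates, seed %d", sc.replicates, sc.seed)
        trees = heuristic_search(coded, sc)
        stats = tree_stats(trees, coded)
        log.info("best length %d, %d trees, CI %.3f, RI %.3f",
                 trees.length, trees.n_trees, stats.ci_display, stats.ri_display)
        agio.write_trees(trees, out / "mpts.nwk", root_label=coded.outgroup)

        stage = "consensus"
        cons = majority_consensus(trees, cutoff=config.consensus_cutoff)
        optimize_characters(cons, coded)
        (out / "consensus.nwk").write_text(cons.newick() + "\n")
        _write_change_table(cons, out / "consensus_changes.csv")

        stage = "endemism"
        report = detect_endemism(matrix, cons, threshold=config.endemism_threshold)
        (out / "endemism.json").write_text(
            json.dumps(report.to_records(), indent=1) + "\n"
        )

        summary = {
            "seed": config.seed,
            "n_areas": len(matrix.areas),
            "n_characters": len(coded.characters),
            "bpa": bool(config.taxon_tree_path),
            "length": trees.length,
            "n_trees": trees.n_trees,
            "hit_max_trees": trees.hit_max_trees,
            "ci": stats.ci_display,
            "ri": stats.ri_display,
            "consensus_nodes": cons.n_nodes,
            "consensus_newick": cons.newick(),
            "endemism": report.to_records(),
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=1) + "\n")
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _write_change_table(cons, path: Path) -> None:
    rows = cons.change_table()
    lines = ["node,character,change,ambiguous"]
    for r in rows:
        lines.append(f"\"{r['node']}\",{r['character']},{r['change']},{int(r['ambiguous'])}")
    path.write_text("\n".join(lines) + "\n")
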