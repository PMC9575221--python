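"""Top-level benchmark pipeline and run configuration.

``run_benchmark`` chains the full evaluation: spatial tendency of the L-R
database on the slide, near/far classification of cell-type pairs, expected
ranked lists, per-tool DES, and consensus accuracy metrics.  All artifacts
are written as TSV/JSON under the output directory together with a run log
capturing parameters, seed and package versions, so a report can be
reproduced byte-for-byte from its config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .celltype_pairs import all_pair_distances, classify_pairs, pairs_frame
from .consensus import accuracy_vs_reference, build_consensus
from .des import build_expected_lists, rank_tools, tool_des
from .io import read_annotation, read_predictions, read_spatial_expression
from .lr_database import expand_multisubunit, filter_by_coverage, load_database
from .tendency import compute_tendency, normalize_counts, tendency_frame

__all__ = ["RunConfig", "run_benchmark"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and parameters of one benchmark run.

    Numeric defaults follow the reference protocol: 1000 permutations,
    Sinkhorn regularization 0.001, top 10% tendency cutoff at one-sided
    P < 0.01, consensus threshold of 3 tools, top-10 baseline predictions
    per direction.
    """

    st_counts: str
    st_coords: str
    lr_db: str
    annotation: str
    predictions: list[str] = field(default_factory=list)
    st_features: str | None = None
    st_barcodes: str | None = None
    out_dir: str = "benchmark_out"
    n_perm: int = 1000
    reg: float = 0.001
    top_fraction: float = 0.10
    alpha: float = 0.01
    min_tools: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.top_fraction < 1:
            raise ValueError("top_fraction must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 1 or self.min_tools < 1:
            raise ValueError("counts must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Flat key-value config file mirroring the CLI flags; keyword
        overrides win over file values."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_benchmark(cfg: RunConfig) -> dict:
    """Execute the full evaluation workflow and write all artifacts.

    Returns the JSON-ready report dict (also written to ``report.json``).
    Any stage failure is re-raised annotated with the stage name.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        stage = "load inputs"
        st = read_spatial_expression(
            cfg.st_counts, cfg.st_coords, cfg.st_features, cfg.st_barcodes
        )
        db = expand_multisubunit(load_database(cfg.lr_db))
        ann = read_annotation(cfg.annotation)
        tables = [read_predictions(p) for p in cfg.predictions]
        logger.info(
            "loaded %d spots, %d genes, %d interactions, %d tools",
            st.n_spots, st.n_genes, len(db), len(tables),
        )

        stage = "spatial tendency"
        st_norm = normalize_counts(st)
        covered = filter_by_coverage(db, st_norm)
        logger.info("%d interactions pass the coverage filter", len(covered))
        tendency = compute_tendency(
            st_norm, covered,
            n_perm=cfg.n_perm, reg=cfg.reg, seed=cfg.seed,
            top_fraction=cfg.top_fraction, alpha=cfg.alpha,
        )
        tendency_frame(tendency).to_csv(out / "tendency.tsv", sep="\t", index=False)

        stage = "cell-type pairs"
        pairs = classify_pairs(all_pair_distances(ann, st.coords), seed=cfg.seed)
        pairs_frame(pairs).to_csv(out / "pairs.tsv", sep="\t", index=False)

        stage = "distance enrichment score"
        L_s, L_l = build_expected_lists(tendency)
        des_results = rank_tools([tool_des(t, pairs, L_s, L_l) for t in tables]) if tables else []
        des_rows = [
            {"tool": r.tool_name, "mean_des": r.mean_des, "rank": r.rank}
            for r in des_results
        ]
        pd.DataFrame(des_rows).to_csv(out / "des.tsv", sep="\t", index=False)

        stage = "consensus metrics"
        metrics_rows = []
        if len(tables) >= cfg.min_tools:
            consensus = build_consensus(tables, min_tools=cfg.min_tools)
            consensus.to_frame().to_csv(out / "consensus.tsv", sep="\t", index=False)
            for t in tables:
                m = accuracy_vs_reference(t, consensus)
                metrics_rows.append(
                    {
                        "tool": m.tool_name,
                        "precision": m.precision,
                        "recall": m.recall,
                        "f1": m.f1,
                        "tp": m.tp,
                        "fp": m.fp,
                        "fn": m.fn,
                        "micro_f1": m.micro_f1,
                    }
                )
        else:
            logger.warning(
                "%d prediction tables < min_tools=%d; consensus skipped",
                len(tables), cfg.min_tools,
            )
        pd.DataFrame(metrics_rows).to_csv(out / "metrics.tsv", sep="\t", index=False)

        stage = "report"
        n_by_class = tendency_frame(tendency)["range_class"].value_counts().to_dict()
        report = {
            "version": __version__,
            "config": dataclasses.asdict(cfg),
            "config_digest": cfg.digest(),
            "seed": cfg.seed,
            "n_interactions_tested": len(covered),
            "range_counts": n_by_class,
            "pair_counts": pairs_frame(pairs)["pair_class"].value_counts().to_dict(),
            "des": des_rows,
            "metrics": metrics_rows,
        }
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        return report
    except Exception as exc:
        raise RuntimeError(f"benchmark failed at stage {stage!r}: {exc}") from exc
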