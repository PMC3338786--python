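"""Configuration-driven end-to-end benchmark runs.

One :class:`RunConfig` describes a full experiment grid — reference
source, primer panel, read lengths, error rates, classification methods,
search scenario, thresholds — and :func:`run_benchmark` executes
generate -> simulate -> classify -> evaluate, returning all assignments
and a long-format metrics table, optionally writing a reproducible
bundle (FASTA, TSVs, JSON manifest) to disk.

A single root seed fans out to per-stage child seeds by stable hashing
of stage labels, so adding a method or length never perturbs the
randomness of the other cells.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from . import __version__
from .classifiers import (
    LcaClassifier,
    NaiveBayesKmerClassifier,
    NjPlacementClassifier,
    apply_confidence_threshold,
    write_assignments_tsv,
)
from .classifiers.base import Assignment
from .evaluation import EvaluationSummary, evaluate, summaries_to_frame
from .reads import LSU_PRIMERS, SimulatedRead, build_mock_communities
from .refdb import ReferenceDB, load_references, write_references
from .seeding import child_seed
from .simulate import SimConfig, generate_database
from .taxonomy import Lineage, RANKS

logger = logging.getLogger("lsubench")

__all__ = ["RunConfig", "RunResult", "run_benchmark", "truncate_by_confidence"]

_METHODS = ("nbc", "lca", "nj")


def truncate_by_confidence(a: Assignment, cutoff: float) -> Assignment:
    """Clear ranks whose confidence/support falls below ``cutoff``."""
    if a.confidences is None or not a.is_classified:
        return a
    keep = 0
    for c in a.confidences:
        if c < cutoff:
            break
        keep += 1
    return Assignment(
        query_id=a.query_id,
        lineage=Lineage(a.lineage.names[:keep]),
        confidences=a.confidences[:keep],
        query_length=a.query_length,
        note=a.note if keep else (a.note + " below support cutoff").strip(),
    )


@dataclass
class RunConfig:
    """The experiment grid for one benchmark run."""

    reference_fasta: Optional[str] = None        # or synthesize:
    sim: SimConfig = field(default_factory=SimConfig)
    primer_names: tuple[str, ...] = ("LR0R", "LR3", "LR5", "LR7")
    lengths: tuple[int, ...] = (50, 100, 200, 400)
    rates: tuple[float, ...] = (0.0,)
    methods: tuple[str, ...] = _METHODS
    scenario: str = "leave_one_out"              # or "complete"
    apply_thresholds: bool = False
    nj_support_cutoff: float = 0.95
    ranks: tuple[str, ...] = RANKS
    max_parents: Optional[int] = 33
    nbc_bootstrap: int = 100
    nj_bootstrap: int = 100
    seed: int = 0
    outdir: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.methods or not self.lengths or not self.rates:
            raise ValueError("methods, lengths and rates must be non-empty")
        unknown = set(self.methods) - set(_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if self.scenario not in ("complete", "leave_one_out"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if 0.0 not in self.rates:
            raise ValueError("rates must include 0 (baseline)")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in raw.items()})
        if sim_raw:
            cfg.sim = SimConfig(**sim_raw)
        return cfg


@dataclass
class RunResult:
    """Everything a run produced, in memory."""

    config: RunConfig
    db: ReferenceDB
    parents: dict[int, list[str]]                      # length -> parent ids
    communities: dict[tuple[int, str, float], list[SimulatedRead]]
    assignments: dict[tuple[str, int, str, float], list[Assignment]]
    summaries: list[EvaluationSummary]
    truths: dict[str, Lineage]

    def metrics_frame(self):
        return summaries_to_frame(self.summaries)


def _fit_classifiers(cfg: RunConfig, db: ReferenceDB):
    est = {}
    if "nbc" in cfg.methods:
        est["nbc"] = NaiveBayesKmerClassifier(
            n_bootstrap=cfg.nbc_bootstrap,
            random_state=child_seed(cfg.seed, "nbc"),
        ).fit(db)
    if "lca" in cfg.methods:
        est["lca"] = LcaClassifier(min_score="auto").fit(db)
    if "nj" in cfg.methods:
        est["nj"] = NjPlacementClassifier(
            n_bootstrap=cfg.nj_bootstrap,
            random_state=child_seed(cfg.seed, "nj"),
        ).fit(db)
    return est


def _classify_cell(
    method: str,
    estimator,
    reads: Sequence[SimulatedRead],
    cfg: RunConfig,
    cell_seed: int,
) -> list[Assignment]:
    exclude = (
        [r.parent_id for r in reads]
        if cfg.scenario == "leave_one_out" else None
    )
    if method == "nbc":
        rng = np.random.default_rng(cell_seed)
        out = [
            estimator.classify_one(r.seq, query_id=r.id, exclude_id=ex, rng=rng)
            for r, ex in zip(reads, exclude or [None] * len(reads))
        ]
        if cfg.apply_thresholds:
            out = [apply_confidence_threshold(a) for a in out]
        return out
    if method == "lca":
        return estimator.predict_assignments(reads, exclude_ids=exclude)
    if method == "nj":
        estimator.random_state = cell_seed
        out = estimator.predict_assignments(reads, exclude_ids=exclude)
        if cfg.apply_thresholds:
            out = [truncate_by_confidence(a, cfg.nj_support_cutoff) for a in out]
        return out
    raise ValueError(f"unknown method {method!r}")  # pragma: no cover


def run_benchmark(cfg: RunConfig, db: Optional[ReferenceDB] = None) -> RunResult:
    """Execute the configured grid; write a bundle if cfg.outdir is set.

    Stage logs go to the ``lsubench`` logger (stderr under the CLI) and,
    when an output directory is configured, to ``<outdir>/run.log``.
    """
    handler: Optional[logging.FileHandler] = None
    if cfg.outdir:
        Path(cfg.outdir).mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(Path(cfg.outdir) / "run.log")
        handler.setFormatter(logging.Formatter(
            "%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    try:
        return _run_benchmark(cfg, db)
    finally:
        if handler is not None:
            logger.removeHandler(handler)
            handler.close()


def _run_benchmark(cfg: RunConfig, db: Optional[ReferenceDB]) -> RunResult:
    if db is None:
        if cfg.reference_fasta:
            logger.info("loading references from %s", cfg.reference_fasta)
            db = load_references(cfg.reference_fasta)
        else:
            logger.info("generating synthetic references (%d species)",
                        cfg.sim.species_count)
            sim = dataclasses.replace(cfg.sim, seed=child_seed(cfg.seed, "sim"))
            db = generate_database(sim)

    primers = [p for p in LSU_PRIMERS if p.name in cfg.primer_names]
    if len(primers) != len(cfg.primer_names):
        missing = set(cfg.primer_names) - {p.name for p in primers}
        raise ValueError(f"unknown primers: {sorted(missing)}")

    estimators = _fit_classifiers(cfg, db)

    parents: dict[int, list[str]] = {}
    communities: dict[tuple[int, str, float], list[SimulatedRead]] = {}
    for L in cfg.lengths:
        comms, retained = build_mock_communities(
            db, primers, L, cfg.rates,
            seed=child_seed(cfg.seed, "reads", L),
            max_parents=cfg.max_parents,
        )
        parents[L] = retained
        for (pname, rate), reads in comms.items():
            communities[(L, pname, rate)] = reads
        logger.info("length %d: %d parents pass all primers", L, len(retained))

    truths: dict[str, Lineage] = {}
    for reads in communities.values():
        for r in reads:
            truths[r.id] = db[r.parent_id].lineage

    assignments: dict[tuple[str, int, str, float], list[Assignment]] = {}
    summaries: list[EvaluationSummary] = []
    for method in cfg.methods:
        for (L, pname, rate), reads in communities.items():
            cell_seed = child_seed(cfg.seed, "classify", method, pname, L,
                                   repr(rate), cfg.scenario)
            result = _classify_cell(method, estimators[method], reads, cfg,
                                    cell_seed)
            assignments[(method, L, pname, rate)] = result
            labels = {"method": method, "primer": pname, "length": L,
                      "rate": rate, "scenario": cfg.scenario}
            summaries.append(
                evaluate(result, truths, ranks=cfg.ranks, labels=labels)
            )
            logger.info("classified %-3s L=%-4d %-5s r=%-6g", method, L,
                        pname, rate)

    result = RunResult(config=cfg, db=db, parents=parents,
                       communities=communities, assignments=assignments,
                       summaries=summaries, truths=truths)
    if cfg.outdir:
        _write_bundle(result, Path(cfg.outdir))
    return result


def _write_bundle(result: RunResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    write_references(result.db, outdir / "references.fasta")
    result.metrics_frame().to_csv(outdir / "metrics.tsv", sep="\t", index=False)
    adir = outdir / "assignments"
    adir.mkdir(exist_ok=True)
    for (method, L, pname, rate), assigns in result.assignments.items():
        name = f"{method}_L{L}_{pname}_r{rate:g}.tsv"
        write_assignments_tsv(assigns, adir / name)
    manifest = {
        "tool": "lsubench",
        "version": __version__,
        "seed": cfg.seed,
        "scenario": cfg.scenario,
        "methods": list(cfg.methods),
        "primers": list(cfg.primer_names),
        "lengths": list(cfg.lengths),
        "rates": list(cfg.rates),
        "apply_thresholds": cfg.apply_thresholds,
        "max_parents": cfg.max_parents,
        "n_references": len(result.db),
        "parents_per_length": {str(k): v for k, v in result.parents.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("bundle written to %s", outdir)
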