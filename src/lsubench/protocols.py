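"""Predefined benchmark protocols on the default synthetic study system.

Each function runs one self-contained experiment on the default 64-species
synthetic reference database (four-primer panel, 33-parent mock
communities) and returns plain dictionaries of computed quantities:
primer-coordinate recovery on the synthetic coordinate scaffold, genus
recovery by read length and method, complete vs leave-one-out search
gaps, statistical-cutoff effects, error-rate degradation tracking, the
per-base error model's goodness of fit, the parent-sequence identity
check, and community-distance / NMDS structure. These are the quantities
the package's reproducibility script and acceptance tests consume.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .classifiers import (
    Assignment,
    LcaClassifier,
    apply_confidence_threshold,
)
from .community import distance_matrix, nmds, normalize_sizes, pool, profile
from .evaluation import evaluate, track_error_degradation
from .orchestrator import RunConfig, run_benchmark, truncate_by_confidence
from .reads import LSU_PRIMERS, inject_errors
from .refdb import ReferenceDB
from .seeding import child_seed
from .simulate import SimConfig, generate_database, primer_reference_scaffold
from .taxonomy import CORRECT, RANKS, compare_at_rank

__all__ = [
    "default_database",
    "primer_mapping_report",
    "length_trend_report",
    "scenario_gap_report",
    "cutoff_effect_report",
    "error_trend_report",
    "binomial_error_report",
    "identity_check_report",
    "community_report",
    "nmds_embedding_report",
]

ERROR_RATES = (0.0, 1e-4, 1e-3, 1e-2, 0.1)
LENGTHS = (50, 100, 200, 400)

# computed grids are reused across reports within one process
_CACHE: dict = {}


def default_database(seed: int) -> ReferenceDB:
    """The 64-species default synthetic reference set for a given seed."""
    key = ("db", seed)
    if key not in _CACHE:
        _CACHE[key] = generate_database(SimConfig(seed=child_seed(seed, "sim")))
    return _CACHE[key]


def _grid(seed, lengths, rates, methods, scenario, thresholds=False,
          nbc_b=0, nj_b=0, max_parents=None):
    key = ("grid", seed, lengths, rates, methods, scenario, thresholds,
           nbc_b, nj_b, max_parents)
    if key not in _CACHE:
        cfg = RunConfig(lengths=lengths, rates=rates, methods=methods,
                        scenario=scenario, apply_thresholds=thresholds,
                        nbc_bootstrap=nbc_b, nj_bootstrap=nj_b, seed=seed,
                        max_parents=max_parents)
        _CACHE[key] = run_benchmark(cfg, db=default_database(seed))
    return _CACHE[key]


def _parent_assignments(seed: int, length: int = 200):
    """Community parents classified (complete search, LCA) at full length."""
    key = ("parents", seed, length)
    if key not in _CACHE:
        from .reads import benchmark_primers, build_mock_communities

        db = default_database(seed)
        _, parents = build_mock_communities(
            db, benchmark_primers(), length, (0.0,),
            seed=child_seed(seed, "reads", length), max_parents=33)
        est = LcaClassifier(min_score="auto").fit(db)
        assigns = est.predict_assignments([db[p].seq for p in parents],
                                          ids=parents)
        _CACHE[key] = (parents, assigns)
    return _CACHE[key]


def primer_mapping_report(seed: int = 0) -> dict[str, float]:
    """Locate every published LSU primer on the synthetic coordinate scaffold.

    The scaffold embeds each primer footprint at its published 1-based
    coordinate; the finder must recover start, end, and strand from
    sequence alone (one mismatch allowed, IUPAC-aware, both strands).
    """
    from .reads import find_primer_site

    scaffold = primer_reference_scaffold()
    out: dict[str, float] = {}
    for primer in LSU_PRIMERS:
        site = find_primer_site(scaffold, primer, max_mismatch=1)
        key = primer.name.lower().replace("-", "")
        if site is None:
            out[f"primer_start_{key}"] = -1.0
            out[f"primer_end_{key}"] = -1.0
            continue
        # report in the published 5'->3' convention: descending for
        # minus-strand (reverse) sites
        if site.strand == "+":
            out[f"primer_start_{key}"] = float(site.start)
            out[f"primer_end_{key}"] = float(site.end)
        else:
            out[f"primer_start_{key}"] = float(site.end)
            out[f"primer_end_{key}"] = float(site.start)
    return out


def _mean_metric(summaries, method: str, length: int, rank: str,
                 metric: str) -> float:
    vals = [s.metric(rank, metric) for s in summaries
            if s.labels["method"] == method and s.labels["length"] == length]
    return float(np.mean(vals))


def length_trend_report(seed: int = 0) -> dict[str, float]:
    """Genus recovery by read length for all three methods (leave-one-out).

    Means across the four-primer panel at error rate 0, mirroring the
    read-length series of the benchmark.
    """
    result = _grid(seed, LENGTHS, (0.0,), ("nbc", "lca", "nj"),
                   "leave_one_out")
    out = {}
    for method in ("nbc", "lca", "nj"):
        for L in LENGTHS:
            out[f"genus_recovery_{method}_L{L}"] = _mean_metric(
                result.summaries, method, L, "genus", "recovery")
    return out


def scenario_gap_report(seed: int = 0, length: int = 200) -> dict[str, float]:
    """Complete vs leave-one-out genus recovery at one read length."""
    out = {}
    complete = _grid(seed, (length,), (0.0,), ("nbc", "lca", "nj"), "complete")
    loo = _grid(seed, LENGTHS, (0.0,), ("nbc", "lca", "nj"), "leave_one_out")
    for tag, result in (("complete", complete), ("loo", loo)):
        for method in ("nbc", "lca", "nj"):
            out[f"genus_recovery_{method}_{tag}"] = _mean_metric(
                result.summaries, method, length, "genus", "recovery")
    return out


def cutoff_effect_report(seed: int = 0, length: int = 200) -> dict[str, float]:
    """Effect of the default statistical cutoffs (NJ 95% support; NBC
    length-dependent confidence) on genus recovery and coverage."""
    result = _grid(seed, (length,), (0.0,), ("nbc", "nj"), "leave_one_out",
                   thresholds=False, nbc_b=100, nj_b=100)
    out = {}
    for method in ("nbc", "nj"):
        plain: list[Assignment] = []
        cut: list[Assignment] = []
        for (m, L, pname, rate), assigns in result.assignments.items():
            if m != method:
                continue
            plain.extend(assigns)
            if method == "nj":
                cut.extend(truncate_by_confidence(a, 0.95) for a in assigns)
            else:
                cut.extend(apply_confidence_threshold(a) for a in assigns)
        for tag, batch in (("", plain), ("_cutoff", cut)):
            s = evaluate(batch, result.truths, ranks=("genus",))
            out[f"{method}_genus_recovery{tag}"] = s.metric("genus", "recovery")
            out[f"{method}_genus_coverage{tag}"] = s.metric("genus", "coverage")
    return out


def error_trend_report(seed: int = 0, length: int = 200) -> dict[str, float]:
    """Tracked recovery change under per-base error, per method.

    Reads correctly classified at 0% error are followed across the error
    series; deltas are means over the four primers. The composition
    classifier is scored with its recommended 50% confidence cutoff for
    short fragments; the LCA classifier has no confidence to threshold.
    """
    result = _grid(seed, (length,), ERROR_RATES, ("nbc", "lca"),
                   "leave_one_out", thresholds=True, nbc_b=100,
                   max_parents=33)
    out = {}
    primers = result.config.primer_names
    for method in ("nbc", "lca"):
        deltas_per_rate: dict[float, list[float]] = {r: [] for r in ERROR_RATES}
        for pname in primers:
            by_rate: dict[float, list[Assignment]] = {}
            truths = {}
            for rate in ERROR_RATES:
                assigns = result.assignments[(method, length, pname, rate)]
                renamed = []
                for a in assigns:
                    base = a.query_id.rsplit("|", 1)[0]
                    renamed.append(Assignment(
                        query_id=base, lineage=a.lineage,
                        confidences=a.confidences,
                        query_length=a.query_length, note=a.note))
                    truths[base] = result.truths[a.query_id]
                by_rate[rate] = renamed
            deltas = track_error_degradation(by_rate, truths, rank="genus")
            for r, d in deltas.items():
                deltas_per_rate[r].append(d)
            n_tracked = sum(
                1 for a in by_rate[0.0]
                if compare_at_rank(a.lineage, truths[a.query_id],
                                   "genus") == CORRECT
            )
            out[f"tracked_{method}"] = out.get(f"tracked_{method}", 0.0) \
                + float(n_tracked)
        for r in ERROR_RATES:
            key = f"recovery_delta_{method}_r{r:g}"
            out[key] = float(np.mean(deltas_per_rate[r]))
    return out


def binomial_error_report(seed: int = 0, length: int = 10_000,
                          n_seeds: int = 150) -> dict[str, float]:
    """Goodness of fit of substitution counts to Binomial(L, r).

    For each study error rate, ``n_seeds`` independent reads of ``length``
    bases are mutated and the count distribution is chi-square-tested
    against the binomial expectation (tails pooled to expected >= 5).
    """
    base = "A" * length
    out = {}
    for rate in (1e-4, 1e-3, 1e-2, 0.1):
        counts = []
        for i in range(n_seeds):
            rng = np.random.default_rng(child_seed(seed, "binom", repr(rate), i))
            _, c = inject_errors(base, rate, rng)
            counts.append(c)
        counts = np.asarray(counts)
        dist = stats.binom(length, rate)
        # bin edges with expected counts >= 5
        lo, hi = int(dist.ppf(1e-6)), int(dist.ppf(1 - 1e-6)) + 1
        edges = [lo]
        acc = 0.0
        for k in range(lo, hi + 1):
            acc += dist.pmf(k) * n_seeds
            if acc >= 5:
                edges.append(k + 1)
                acc = 0.0
        if len(edges) < 3:  # tiny support: test the two-bin split at the mode
            edges = [lo, int(dist.ppf(0.5)) + 1, hi + 1]
        else:
            edges[-1] = hi + 1
        observed, _ = np.histogram(counts, bins=edges)
        cdf = np.array([dist.cdf(e - 1) for e in edges])
        expected = np.diff(np.concatenate([[dist.cdf(edges[0] - 1)], cdf[1:]]))
        expected = expected / expected.sum() * n_seeds
        keep = expected > 0
        chi2 = float(((observed[keep] - expected[keep]) ** 2
                      / expected[keep]).sum())
        dof = max(1, int(keep.sum()) - 1)
        p = float(stats.chi2.sf(chi2, dof))
        out[f"error_binomial_p_r{rate:g}"] = p
        out[f"error_mean_count_r{rate:g}"] = float(counts.mean())
    return out


def identity_check_report(seed: int = 0) -> dict[str, float]:
    """Parent-length sequences vs the complete database through the LCA
    classifier: the number of rank-level classification errors (expect 0)."""
    db = default_database(seed)
    parents, assigns = _parent_assignments(seed)
    errors = 0
    for a in assigns:
        truth = db[a.query_id].lineage
        for rank in RANKS:
            if truth.has_rank(rank):
                status = compare_at_rank(a.lineage, truth, rank)
                if status == "incorrect":
                    errors += 1
    return {
        "parent_misclassified_rank_calls": float(errors),
        "parent_queries": float(len(parents)),
    }


def community_report(seed: int = 0, length: int = 200,
                     rank: str = "genus") -> dict[str, float]:
    """Rank-level community structure under primer choice and error.

    Builds rank-level profiles for every (primer, error rate) mock
    community under both classifiers. The summary rank defaults to genus:
    it is the most inclusive rank at which the synthetic taxonomy still
    shows differential detection between primers (at order and above the
    eight-order default taxonomy is recovered perfectly by every primer,
    so all profiles coincide). Profiles are normalized, normalizes sizes, computes
    Bray-Curtis and taxonomy-UniFrac distances, ordinates with NMDS, and
    summarizes the structural comparisons: between-primer vs within-primer
    distances, distance of high-error communities from their own
    zero-error points, and the pooled four-primer dataset vs the
    reference (parent) community.
    """
    db = default_database(seed)
    result = _grid(seed, (length,), ERROR_RATES, ("nbc", "lca"),
                   "leave_one_out", thresholds=True, nbc_b=100,
                   max_parents=33)
    primers = result.config.primer_names
    tax = db.taxonomy
    out: dict[str, float] = {}

    # reference community: parent sequences, complete search, LCA
    parents, ref_assigns = _parent_assignments(seed, length)
    ref_profile = profile(ref_assigns, rank, tax, label="reference")

    for method in ("nbc", "lca"):
        profiles = {}
        for pname in primers:
            for rate in ERROR_RATES:
                assigns = result.assignments[(method, length, pname, rate)]
                profiles[(pname, rate)] = profile(
                    assigns, rank, tax, label=f"{pname}_r{rate:g}")
        labels = list(profiles)
        norm = normalize_sizes([profiles[k] for k in labels])
        profiles = dict(zip(labels, norm))

        for metric in ("bray_curtis", "unifrac"):
            def dist(a, b):
                return distance_matrix([a, b], metric=metric,
                                       taxonomy=tax).values[0, 1]

            between = [
                dist(profiles[(p1, 0.0)], profiles[(p2, 0.0)])
                for i, p1 in enumerate(primers) for p2 in primers[i + 1:]
            ]
            within = [
                dist(profiles[(p, 0.0)], profiles[(p, r)])
                for p in primers for r in (1e-4, 1e-3)
            ]
            drift_small = [
                dist(profiles[(p, 0.0)], profiles[(p, r)])
                for p in primers for r in (1e-4, 1e-3, 1e-2)
            ]
            drift_large = [
                dist(profiles[(p, 0.0)], profiles[(p, 0.1)]) for p in primers
            ]
            tag = f"{method}_{'bc' if metric == 'bray_curtis' else 'uf'}"
            out[f"{tag}_between_primer_mean"] = float(np.mean(between))
            out[f"{tag}_within_primer_mean"] = float(np.mean(within))
            out[f"{tag}_drift_r0.1_mean"] = float(np.mean(drift_large))
            out[f"{tag}_drift_smaller_max"] = float(np.max(drift_small))

        # NMDS of the full (primer x rate) + reference + pooled set
        pooled = pool([profiles[(p, 0.0)] for p in primers], label="pooled")
        all_profiles = [ref_profile] + [profiles[k] for k in labels] + [pooled]
        all_profiles = normalize_sizes(all_profiles)
        dmat = distance_matrix(all_profiles, metric="bray_curtis",
                               taxonomy=tax)
        coords, stress = nmds(dmat, random_state=child_seed(seed, "nmds",
                                                            method))
        out[f"{method}_nmds_stress"] = float(stress)
    return out


def nmds_embedding_report(seed: int = 0) -> dict[str, float]:
    """NMDS sanity quantities: stress on an exactly embeddable distance set."""
    pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    from .community import DistanceMatrix

    dmat = DistanceMatrix(("a", "b", "c", "d"), d / d.max())
    coords, stress = nmds(dmat, random_state=child_seed(seed, "nmds-embed"))
    return {"nmds_stress_exact_embedding": float(stress)}
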