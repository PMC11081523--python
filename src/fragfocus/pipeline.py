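"""End-to-end desk-scale pipeline: generate → mine → featurize → train → screen.

This is the orchestration layer used by the worked example and the
reproduction script.  Problem sizes default to the packaged desk-scale
benchmark: a 500-compound labeled set (1:9 imbalance), a 990-compound
assumed-inactive pool, a 10,000-compound screening stream with 1% planted
actives, fragment library capped at the 266 highest-support fragments, and
reduced member tuning (20 random-search trials, 5 CV folds).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from fragfocus.chem_io import Dataset
from fragfocus.ensemble import (
    EnsembleModel,
    EvaluationMetrics,
    TuningConfig,
    evaluate,
    labels_to_y,
    negative_pool_fpr,
    split_train_test,
    train_ensemble,
)
from fragfocus.featurizer import FeaturizerConfig, featurize
from fragfocus.fragment_miner import FragmentLibrary, MiningConfig, mine_fragments
from fragfocus.screener import ScreeningReport, screen_library
from fragfocus.synthetic_data import (
    BenchmarkConfig,
    generate_benchmark,
    generate_negative_pool,
    generate_screening_stream,
    is_planted,
)


@dataclass
class PipelineResult:
    """Artifacts and measurements from one benchmark pipeline run."""

    benchmark: Dataset
    scaffolds: list[str]
    library: FragmentLibrary
    n_fragments_mined: int
    model: EnsembleModel
    member_metrics: dict[str, EvaluationMetrics]
    ensemble_metrics: EvaluationMetrics
    negative_fpr: dict[int, float]
    screening_report: ScreeningReport
    focused: Dataset
    stream_planted_fraction: float
    focused_planted_fraction: float
    enrichment: float
    recovered_scaffolds: list[str] = field(default_factory=list)


def run_benchmark_pipeline(
    seed: int = 0,
    benchmark_cfg: Optional[BenchmarkConfig] = None,
    mining_cfg: MiningConfig = MiningConfig(),
    featurizer_cfg: FeaturizerConfig = FeaturizerConfig(),
    library_cap: int = 266,
    n_trials: int = 20,
    cv_folds: int = 5,
    negative_pool_size: int = 990,
    stream_size: int = 10_000,
    planted_fraction: float = 0.01,
    vote_threshold: int = 6,
) -> PipelineResult:
    """Run the full pipeline on a seeded synthetic benchmark and measure it."""
    bench_cfg = benchmark_cfg if benchmark_cfg is not None else BenchmarkConfig(seed=seed)
    benchmark, scaffolds = generate_benchmark(bench_cfg)
    actives = benchmark.subset("active")
    inactives = benchmark.subset("inactive")

    full_library = mine_fragments(actives, inactives, mining_cfg, provenance=benchmark.name)
    library = full_library.top(library_cap)
    recovered = [s for s in scaffolds if _scaffold_in_library(s, full_library)]

    X = featurize(benchmark, library, featurizer_cfg)
    y = labels_to_y([r.label for r in benchmark])
    X_train, X_test, y_train, y_test = split_train_test(X, y, fraction=0.9, seed=seed)
    tuning = TuningConfig(n_trials=n_trials, cv_folds=cv_folds, seed=seed)
    model = train_ensemble(X_train, y_train, tuning=tuning, vote_threshold=vote_threshold)

    member_metrics = {alg: evaluate(est, X_test, y_test)[0] for alg, est in model.members.items()}
    ensemble_metrics, _ = evaluate(model, X_test, y_test)

    pool = generate_negative_pool(negative_pool_size, seed=seed, exclude=benchmark.smiles)
    fpr = negative_pool_fpr(model, featurize(pool, library, featurizer_cfg))

    stream = generate_screening_stream(stream_size, planted_fraction, seed=seed)
    focused, report = screen_library(stream, library, model, vote_threshold, featurizer_cfg)
    stream_rate = float(np.mean([is_planted(smi, scaffolds) for _, smi in stream]))
    focused_rate = (
        float(np.mean([is_planted(r.smiles, scaffolds) for r in focused])) if len(focused) else 0.0
    )
    enrichment = focused_rate / stream_rate if stream_rate > 0 else float("nan")

    return PipelineResult(
        benchmark=benchmark,
        scaffolds=scaffolds,
        library=library,
        n_fragments_mined=len(full_library),
        model=model,
        member_metrics=member_metrics,
        ensemble_metrics=ensemble_metrics,
        negative_fpr=fpr,
        screening_report=report,
        focused=focused,
        stream_planted_fraction=stream_rate,
        focused_planted_fraction=focused_rate,
        enrichment=enrichment,
        recovered_scaffolds=recovered,
    )


def _scaffold_in_library(scaffold_smiles: str, library: FragmentLibrary) -> bool:
    from fragfocus.fragment_miner import fragment_form

    return fragment_form(scaffold_smiles) in set(library.smiles)
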