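"""Seeded Monte-Carlo experiments over synthetic studies.

These drive the calibration/validation properties of the whole pipeline:
planted-truth recovery sweeps, permutation null for the citation-benchmark
AUC, and the significance-direction experiment on enriched studies.  They
are used both by the test suite and by the reproduction script.
"""

from __future__ import annotations

import dataclasses
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .benchmarks import citation_benchmark
from .pipeline import RunConfig, run_pipeline
from .synthetic import (
    ENRICHED_STUDY_CONFIG,
    GeneratorConfig,
    generate_study,
    verify_truth_recovery,
)

_MOD = 2**31


def _subseed(base: int, i: int) -> int:
    return (base * 1000003 + i) % _MOD


def run_study(config: GeneratorConfig, seed: int, workdir: str | Path):
    """Generate one study and run the full pipeline on it."""
    out = Path(workdir) / f"study_{seed}"
    truth = generate_study(config, seed=seed, outdir=out)
    bundle = run_pipeline(RunConfig.from_json(out / "run.json"))
    return truth, bundle


def truth_recovery_sweep(
    n_seeds: int, base_seed: int = 0, config: GeneratorConfig | None = None
) -> tuple[int, list[int]]:
    """Run the pipeline on n freshly generated studies; return (#pass, failing seeds)."""
    config = config or GeneratorConfig()
    failing: list[int] = []
    with tempfile.TemporaryDirectory() as td:
        for i in range(n_seeds):
            seed = _subseed(base_seed, i)
            truth, bundle = run_study(config, seed, td)
            if not verify_truth_recovery(bundle, truth).passed:
                failing.append(seed)
    return n_seeds - len(failing), failing


@dataclass
class SignificanceResult:
    n_reps: int
    frac_benchmark1: float  # fraction of replicates with p < alpha
    frac_benchmark2: float
    mean_auc1: float
    mean_auc2: float


def enrichment_significance(
    n_reps: int,
    base_seed: int = 0,
    config: GeneratorConfig = ENRICHED_STUDY_CONFIG,
    alpha: float = 0.05,
) -> SignificanceResult:
    """Both benchmarks on repeated enriched studies; fraction significant."""
    sig1 = sig2 = 0
    a1: list[float] = []
    a2: list[float] = []
    code = config.phenotypes[0].code
    with tempfile.TemporaryDirectory() as td:
        for i in range(n_reps):
            seed = _subseed(base_seed, i)
            _, bundle = run_study(config, seed, td)
            c1 = bundle.roc_by_phenotype[code]
            c2 = bundle.citation_roc_by_phenotype[code].curve
            if c1.p_value is not None and c1.p_value < alpha:
                sig1 += 1
            if c2.p_value is not None and c2.p_value < alpha:
                sig2 += 1
            a1.append(c1.auc)
            a2.append(c2.auc)
    return SignificanceResult(
        n_reps=n_reps,
        frac_benchmark1=sig1 / n_reps,
        frac_benchmark2=sig2 / n_reps,
        mean_auc1=float(np.mean(a1)),
        mean_auc2=float(np.mean(a2)),
    )


def permuted_label_auc_mean(
    n_permutations: int = 500,
    seed: int = 0,
    n_space: int = 400,
    n_predicted: int = 100,
    baseline_mean: float = 2.0,
    dispersion: float = 2.0,
) -> float:
    """Mean citation-benchmark AUC when citation labels are shuffled.

    Shuffling destroys any gene–prediction association, so the expected AUC
    is 0.5 regardless of the citation distribution.
    """
    rng = np.random.default_rng(seed % _MOD)
    genes = [f"G{i:05d}" for i in range(n_space)]
    predicted = set(genes[:n_predicted])
    counts = rng.negative_binomial(
        dispersion, dispersion / (dispersion + baseline_mean), size=n_space
    )
    aucs = []
    for _ in range(n_permutations):
        perm = rng.permutation(counts)
        cits = {g: int(c) for g, c in zip(genes, perm)}
        res = citation_benchmark(predicted, genes, cits)
        if res.curve.auc is not None:
            aucs.append(res.curve.auc)
    return float(np.mean(aucs))


def null_citation_auc(
    n_reps: int = 200, base_seed: int = 0, config: GeneratorConfig | None = None
) -> float:
    """Mean citation-benchmark AUC over full studies with no enrichment (r=1)."""
    cfg = dataclasses.replace(config or ENRICHED_STUDY_CONFIG, citation_enrichment=1.0)
    code = cfg.phenotypes[0].code
    aucs = []
    with tempfile.TemporaryDirectory() as td:
        for i in range(n_reps):
            seed = _subseed(base_seed, i)
            _, bundle = run_study(cfg, seed, td)
            aucs.append(bundle.citation_roc_by_phenotype[code].curve.auc)
    return float(np.mean(aucs))
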