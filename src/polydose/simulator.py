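"""Synthetic two-channel intensity data with the model's generative structure.

One simulated locus draws genotype counts from the population model's
multinomial (or i.i.d. genotypes on request), places each replicate's
normalized coordinate at ``N(g/m, sigma^2)`` truncated to [0, 1], and emits
the intensity pair ``(T*r, T*(1-r))`` with the total intensity ``T`` drawn
around a nominal scale.  Because the likelihood depends only on the ratio,
the intensity magnitude model is immaterial to inference; it exists so that
simulated tables look like assay output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_io import LocusDataset, SamplePoint, write_locus
from .population_models import F1Params, f1_frequencies, hw_frequencies


@dataclass(frozen=True)
class SimSpec:
    """Generative settings for one simulated locus.

    ``model`` is ``("hw", p)``, ``("f1", (p1, p2))`` or ``("custom", F)``.
    ``sigma`` is the noise of the normalized coordinate, matching the
    likelihood model; ``raw_channel_noise`` instead perturbs the raw
    channels, deliberately violating the model for robustness studies.
    """

    m: int
    model: tuple
    n: int
    sigma: float
    total_intensity: float = 1000.0
    intensity_spread: float = 0.1
    replicates: int = 1
    parent_replicates: int = 0
    seed: int = 0
    iid_genotypes: bool = False
    raw_channel_noise: bool = False
    locus_id: str = "sim"

    def __post_init__(self) -> None:
        if self.n < 1 or self.sigma <= 0 or self.replicates < 1:
            raise ValueError("need n >= 1, sigma > 0, replicates >= 1")
        kind = self.model[0]
        if kind not in ("hw", "f1", "custom"):
            raise ValueError(f"unknown model kind {kind!r}")
        if kind == "f1" and self.m % 2:
            raise ValueError("F1 model requires even ploidy")

    def frequency_vector(self) -> np.ndarray:
        kind, param = self.model
        if kind == "hw":
            return hw_frequencies(self.m, param)
        if kind == "f1":
            return f1_frequencies(self.m, F1Params(*param))
        return np.asarray(param, dtype=float)


@dataclass
class SimTruth:
    """Ground truth of a simulated locus."""

    genotypes: dict[str, int]
    F: np.ndarray
    spec: SimSpec


def _emit_points(
    rng: np.random.Generator,
    ind_ids: list[str],
    genotypes: np.ndarray,
    spec: SimSpec,
    replicates: int,
) -> list[SamplePoint]:
    points: list[SamplePoint] = []
    for ind, g in zip(ind_ids, genotypes):
        for _ in range(replicates):
            T = spec.total_intensity * rng.lognormal(0.0, spec.intensity_spread)
            if spec.raw_channel_noise:
                x = max(0.0, T * g / spec.m + rng.normal(0.0, spec.sigma * T))
                y = max(0.0, T * (1 - g / spec.m) + rng.normal(0.0, spec.sigma * T))
                if x + y == 0:
                    x = T * 1e-6  # keep the point normalizable
            else:
                r = float(np.clip(rng.normal(g / spec.m, spec.sigma), 0.0, 1.0))
                x, y = T * r, T * (1 - r)
            points.append(SamplePoint(ind, x, y))
    return points


def simulate(spec: SimSpec) -> tuple[LocusDataset, SimTruth]:
    """Draw one locus dataset plus its ground truth, reproducibly by seed."""
    rng = np.random.default_rng(spec.seed)
    F = spec.frequency_vector()
    if spec.iid_genotypes:
        genotypes = rng.choice(spec.m + 1, size=spec.n, p=F)
    else:
        counts = rng.multinomial(spec.n, F)
        genotypes = np.repeat(np.arange(spec.m + 1), counts)
        rng.shuffle(genotypes)
    width = len(str(spec.n - 1))
    ind_ids = [f"ind{str(i).zfill(width)}" for i in range(spec.n)]

    points = _emit_points(rng, ind_ids, genotypes, spec, spec.replicates)

    parent1 = parent2 = None
    if spec.model[0] == "f1" and spec.parent_replicates > 0:
        p1, p2 = spec.model[1]
        parent1 = _emit_points(
            rng, ["P1"], np.array([p1]), spec, spec.parent_replicates
        )
        parent2 = _emit_points(
            rng, ["P2"], np.array([p2]), spec, spec.parent_replicates
        )

    dataset = LocusDataset(
        locus_id=spec.locus_id,
        points=points,
        parent1_points=parent1,
        parent2_points=parent2,
    )
    truth = SimTruth(
        genotypes={ind: int(g) for ind, g in zip(ind_ids, genotypes)},
        F=F,
        spec=spec,
    )
    return dataset, truth


FIXTURE_SPECS: dict[str, SimSpec] = {
    # oracle-size instances for engine-equivalence checks
    "oracle_small_hw": SimSpec(
        m=2, model=("hw", 0.5), n=6, sigma=0.08, seed=11, locus_id="oracle_small_hw"
    ),
    "oracle_small_f1": SimSpec(
        m=4, model=("f1", (1, 0)), n=6, sigma=0.08, seed=12, locus_id="oracle_small_f1"
    ),
    # recovery-study instances
    "recovery_hw_m4": SimSpec(
        m=4, model=("hw", 0.5), n=200, sigma=0.05, seed=21, locus_id="recovery_hw_m4"
    ),
    "recovery_f1_m4": SimSpec(
        m=4,
        model=("f1", (1, 0)),
        n=200,
        sigma=0.05,
        seed=22,
        parent_replicates=12,
        locus_id="recovery_f1_m4",
    ),
    # a sugarcane-like benchmark locus: 180 progeny of a decaploid
    # triplex x nulliplex cross, 12 replicates of each parent
    "benchmark_m10_f1": SimSpec(
        m=10,
        model=("f1", (3, 0)),
        n=180,
        sigma=0.05,
        seed=31,
        parent_replicates=12,
        locus_id="benchmark_m10_f1",
    ),
}


def make_fixture_suite(out_dir: str | Path) -> dict[str, str]:
    """Write the canonical seeded fixture datasets; returns a manifest.

    Running twice produces identical files (all randomness is seeded, and
    intensities are written at full precision).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for name, spec in FIXTURE_SPECS.items():
        dataset, _ = simulate(spec)
        path = out_dir / f"{name}.tsv"
        write_locus(dataset, path)
        manifest[name] = path.name
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
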