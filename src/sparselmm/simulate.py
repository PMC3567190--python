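"""Synthetic GWAS-like data with exact control of the realized variance split.

Genotypes are binomial dosages from per-marker minor-allele frequencies,
with optional local LD induced by copying haplotype alleles within blocks.
Phenotype architectures:

* scenario I  — a fixed number of causal markers with standard-normal
  effects plus rescaled Gaussian noise, so the realized share of variance
  from the genetic component equals the target exactly;
* scenario II — a small group of moderate effects plus a large "polygenic"
  group of tiny effects, with the moderate group's realized share of the
  genetic variance fixed exactly as well.

All rescaling is done on the realized vectors, so every replicate's true
variance decomposition is exact, not just in expectation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .geno_io import GenotypeMatrix, PhenotypeVector, impute_and_center
from .model_core import sample_variance

__all__ = [
    "SimTruth",
    "simulate_genotypes",
    "simulate_scenario1",
    "simulate_scenario2",
    "split_train_test",
    "write_truth",
    "write_manifest",
]


@dataclass
class SimTruth:
    causal_ids: np.ndarray
    beta_true: np.ndarray          # length p
    genetic_component: np.ndarray  # length n
    noise: np.ndarray              # length n
    realized_pve: float
    scenario: str
    group_sizes: tuple[int, ...]
    large_group_share: Optional[float] = None  # scenario II only
    large_ids: Optional[np.ndarray] = None     # scenario II moderate group
    small_ids: Optional[np.ndarray] = None     # scenario II polygenic group


def simulate_genotypes(
    n: int,
    p: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_block: int = 1,
    rng: Optional[np.random.Generator] = None,
    copy_prob: float = 0.7,
) -> GenotypeMatrix:
    """Binomial dosage matrix with optional block-local LD.

    Each marker's MAF is uniform on ``maf_range``; a dosage is the sum of
    two haplotype alleles.  Within a block of ``ld_block`` consecutive
    markers each haplotype allele is copied from the block's first marker
    with probability ``copy_prob``, inducing within-block correlation.
    """
    rng = rng if rng is not None else np.random.default_rng()
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
    if ld_block < 1:
        raise ValueError("ld_block must be >= 1")
    maf = rng.uniform(lo, hi, size=p)
    hap1 = (rng.random((n, p)) < maf[None, :]).astype(np.int8)
    hap2 = (rng.random((n, p)) < maf[None, :]).astype(np.int8)
    if ld_block > 1:
        for start in range(0, p, ld_block):
            stop = min(start + ld_block, p)
            for j in range(start + 1, stop):
                copy1 = rng.random(n) < copy_prob
                copy2 = rng.random(n) < copy_prob
                hap1[copy1, j] = hap1[copy1, start]
                hap2[copy2, j] = hap2[copy2, start]
    dosages = (hap1 + hap2).astype(float)
    ids = [f"rs{j}" for j in range(p)]
    return GenotypeMatrix(dosages=dosages, marker_ids=ids)


def _centered_dosages(g: GenotypeMatrix) -> np.ndarray:
    if g.centered:
        return g.dosages
    return impute_and_center(g).dosages


def _scaled_noise(
    genetic: np.ndarray, target_pve: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise rescaled so V(g)/(V(g)+V(e)) == target exactly."""
    v_g = sample_variance(genetic)
    if v_g <= 0.0:
        raise ValueError("degenerate genetic component")
    e = rng.standard_normal(genetic.size)
    v_e_target = v_g * (1.0 - target_pve) / target_pve
    v_e = sample_variance(e)
    return e * np.sqrt(v_e_target / v_e)


def simulate_scenario1(
    g: GenotypeMatrix,
    S: int,
    target_pve: float,
    rng: np.random.Generator,
) -> tuple[PhenotypeVector, SimTruth]:
    """Fixed number of causal markers, standard-normal effects."""
    if not (0.0 < target_pve < 1.0):
        raise ValueError("target_pve must be in (0, 1)")
    if S > g.p:
        raise ValueError("S exceeds the number of markers")
    X = _centered_dosages(g)
    for _ in range(10):
        causal = np.sort(rng.choice(g.p, size=S, replace=False))
        beta_c = rng.standard_normal(S)
        genetic = X[:, causal] @ beta_c
        if sample_variance(genetic) > 0.0:
            break
    else:
        raise ValueError("could not draw a non-degenerate causal set")
    noise = _scaled_noise(genetic, target_pve, rng)
    y = genetic + noise
    beta_true = np.zeros(g.p)
    beta_true[causal] = beta_c
    v_g = sample_variance(genetic)
    truth = SimTruth(
        causal_ids=causal,
        beta_true=beta_true,
        genetic_component=genetic,
        noise=noise,
        realized_pve=v_g / (v_g + sample_variance(noise)),
        scenario="I",
        group_sizes=(S,),
    )
    return PhenotypeVector(values=y), truth


def simulate_scenario2(
    g: GenotypeMatrix,
    S_large: int,
    S_small: int,
    pge_target: float,
    target_pve: float,
    rng: np.random.Generator,
) -> tuple[PhenotypeVector, SimTruth]:
    """Moderate-effect group plus polygenic background.

    Both groups' effects are drawn standard normal, then the background is
    rescaled so the moderate group's realized share of the total genetic
    variance, V(g_large)/V(g_large + g_small), equals ``pge_target``.
    """
    if S_large + S_small > g.p:
        raise ValueError("S_large + S_small exceeds the number of markers")
    if not (0.0 < target_pve < 1.0 and 0.0 < pge_target < 1.0):
        raise ValueError("targets must be in (0, 1)")
    X = _centered_dosages(g)
    for _ in range(10):
        chosen = rng.choice(g.p, size=S_large + S_small, replace=False)
        large = np.sort(chosen[:S_large])
        small = np.sort(chosen[S_large:])
        b_large = rng.standard_normal(S_large)
        b_small = rng.standard_normal(S_small)
        g_l = X[:, large] @ b_large if S_large else np.zeros(g.n)
        g_s = X[:, small] @ b_small
        if S_large == 0:
            genetic = g_s
            scale_s = 1.0
            share = 0.0
            if sample_variance(genetic) <= 0:
                continue
            break
        v_l = sample_variance(g_l)
        v_s = sample_variance(g_s)
        if v_l <= 0 or v_s <= 0:
            continue
        # choose c > 0 with V(g_l) / V(g_l + c g_s) == pge_target
        gl_c = g_l - g_l.mean()
        gs_c = g_s - g_s.mean()
        cov = float(gl_c @ gs_c) / g.n
        t = pge_target
        disc = cov * cov - v_s * v_l * (1.0 - 1.0 / t)
        scale_s = (-cov + np.sqrt(disc)) / v_s
        genetic = g_l + scale_s * g_s
        share = v_l / sample_variance(genetic)
        break
    else:
        raise ValueError("could not draw a non-degenerate causal set")
    noise = _scaled_noise(genetic, target_pve, rng)
    y = genetic + noise
    beta_true = np.zeros(g.p)
    if S_large:
        beta_true[large] = b_large
    beta_true[small] = scale_s * b_small
    v_g = sample_variance(genetic)
    truth = SimTruth(
        causal_ids=np.sort(np.concatenate([large, small]) if S_large else small),
        beta_true=beta_true,
        genetic_component=genetic,
        noise=noise,
        realized_pve=v_g / (v_g + sample_variance(noise)),
        scenario="II",
        group_sizes=(S_large, S_small),
        large_group_share=share,
        large_ids=large if S_large else np.empty(0, dtype=int),
        small_ids=small,
    )
    return PhenotypeVector(values=y), truth


def split_train_test(
    n: int,
    fraction: float,
    rng: np.random.Generator,
    families: Optional[Sequence] = None,
    mode: str = "random",
) -> tuple[np.ndarray, np.ndarray]:
    """Partition individuals into train/test.

    ``mode='random'`` splits individuals; ``mode='by_group'`` keeps whole
    families on one side so no group label spans the split.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    if mode == "random":
        perm = rng.permutation(n)
        k = int(round(fraction * n))
        return np.sort(perm[:k]), np.sort(perm[k:])
    if mode == "by_group":
        if families is None:
            raise ValueError("by_group split needs family labels")
        fam = np.asarray(families)
        groups = np.unique(fam)
        gperm = rng.permutation(groups)
        train_idx: list[int] = []
        target = fraction * n
        chosen: set = set()
        count = 0
        for gl in gperm:
            if count >= target:
                break
            chosen.add(gl)
            count += int((fam == gl).sum())
        mask = np.isin(fam, list(chosen))
        return np.flatnonzero(mask), np.flatnonzero(~mask)
    raise ValueError(f"unknown split mode {mode!r}")


def write_truth(truth: SimTruth, g: GenotypeMatrix, path) -> None:
    """Per-marker sidecar: id, true beta, causal flag (tab-delimited)."""
    causal = np.zeros(g.p, dtype=bool)
    causal[truth.causal_ids] = True
    with open(path, "w") as fh:
        fh.write("id\tbeta_true\tcausal\n")
        for j in range(g.p):
            fh.write(f"{g.marker_ids[j]}\t{float(truth.beta_true[j])!r}\t{int(causal[j])}\n")


def write_manifest(truth: SimTruth, seed: int, path, **extra) -> None:
    doc = {
        "seed": seed,
        "scenario": truth.scenario,
        "realized_pve": truth.realized_pve,
        "group_sizes": list(truth.group_sizes),
        "n_causal": int(truth.causal_ids.size),
    }
    if truth.large_group_share is not None:
        doc["large_group_share"] = truth.large_group_share
    doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
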