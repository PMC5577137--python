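"""Synthetic breast-tumour cohort generator.

Emulates the statistical structure a label-free proteomics subtype study
relies on, so every downstream stage (preprocessing, SAM, clustering,
graphical models, FBA, classification, survival) is testable without
patient data:

* ~1000 quantifiable proteins, a differential subset separating three
  latent groups — ER-true, TN-like and TNBC — with TN-like sharing the
  TNBC shift direction for a configurable overlap fraction;
* block-correlated protein modules (miRNAs as noisy module readouts);
* missing-not-at-random low-abundance dropout (logistic in abundance
  rank, mimicking MS left-censoring);
* a two-batch additive batch effect;
* group-dependent distant-metastasis-free survival, exponential hazards
  calibrated to 5-year survival probabilities (default 0.882/0.714/0.654).

A Gaussian Markov-tree sampler provides oracle input for the network
module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import ExpressionMatrix

__all__ = ["CohortSpec", "SyntheticCohort", "generate_cohort", "generate_tree_gaussian"]

GROUPS = ("ER-true", "TN-like", "TNBC")


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults correspond to a discovery cohort of 97 tumours (50 ER-true,
    21 TN-like, 26 TNBC), 1095 quantifiable proteins of which 224 carry a
    subtype effect, 90 miRNAs, and 5-year DMFS of 0.882/0.714/0.654 per
    group.  ``effect_size`` is a standardised mean shift in z-units.
    """

    n_per_group: tuple[int, int, int] = (50, 21, 26)
    n_proteins: int = 1095
    n_differential: int = 224
    effect_size: float = 1.5
    n_mirna: int = 90
    missing_rate: float = 0.10
    n_batches: int = 2
    batch_shift: float = 0.5
    surv5: tuple[float, float, float] = (0.882, 0.714, 0.654)
    censor_rate: float = 0.3
    seed: int = 0
    # secondary knobs
    overlap_fraction: float = 0.55   # fraction of TN-like diff. proteins shared with TNBC
    n_tnlike_extra: int = 20         # TN-like-specific differential proteins (outside TNBC set)
    module_size: int = 10            # block-diagonal correlation modules
    module_corr: float = 0.4         # intra-module correlation (assumption, configurable)
    dropout_steepness: float = 8.0   # logistic slope of dropout vs abundance rank
    followup_months: float = 120.0
    baseline_log2_mean: float = 26.0
    baseline_log2_sd: float = 2.0

    def validate(self) -> None:
        counts = (*self.n_per_group, self.n_proteins, self.n_mirna, self.n_batches)
        scalars = (self.effect_size, self.missing_rate, self.batch_shift,
                   self.censor_rate, *self.surv5, self.overlap_fraction)
        if not all(np.isfinite(scalars)):
            raise ValueError("non-finite spec value")
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be > 0")
        if self.n_differential > self.n_proteins:
            raise ValueError("n_differential exceeds n_proteins")
        if not all(0 < s <= 1 for s in self.surv5):
            raise ValueError("surv5 values must lie in (0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")


@dataclass
class SyntheticCohort:
    """A generated cohort: expression, annotation, and ground truth."""

    expression: ExpressionMatrix          # proteins, raw intensity scale, NaN dropout
    mirna: pd.DataFrame                   # miRNAs, normalised (z-like) scale, complete
    annotation: pd.DataFrame              # sample_id-indexed clinical table
    true_labels: pd.Series                # latent group per sample
    true_differential: frozenset          # protein ids with a planted subtype effect
    truth_log2: pd.DataFrame              # complete log2 protein matrix pre-dropout

    def __post_init__(self) -> None:
        if not self.annotation.index.equals(self.expression.sample_ids):
            raise ValueError("annotation rows must match expression columns")


def _dropout_probs(log2_vals: np.ndarray, rate: float, steepness: float) -> np.ndarray:
    """Logistic dropout probability in pooled abundance rank, calibrated
    by bisection so the expected missing fraction equals ``rate``."""
    order = log2_vals.ravel().argsort().argsort()
    u = (order + 0.5) / order.size  # rank quantile in (0,1)

    def mean_p(u0: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(steepness * (u - u0)))))

    lo, hi = -2.0, 3.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if mean_p(mid) < rate:
            lo = mid
        else:
            hi = mid
    u0 = 0.5 * (lo + hi)
    p = 1.0 / (1.0 + np.exp(steepness * (u - u0)))
    return p.reshape(log2_vals.shape)


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a full synthetic cohort from ``spec`` (bit-reproducible by seed)."""
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    rng_expr, rng_mirna, rng_miss, rng_surv = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    n_samples = sum(spec.n_per_group)
    labels = np.repeat(GROUPS, spec.n_per_group)
    sample_ids = pd.Index([f"S{i:03d}" for i in range(n_samples)], name="sample_id")
    protein_ids = pd.Index([f"P{j:04d}" for j in range(spec.n_proteins)])

    # block-correlated residuals: modules of module_size proteins share a factor
    rho = spec.module_corr
    n_modules = math.ceil(spec.n_proteins / spec.module_size)
    module_of = np.arange(spec.n_proteins) // spec.module_size
    factors = rng_expr.standard_normal((n_modules, n_samples))
    eps = rng_expr.standard_normal((spec.n_proteins, n_samples))
    z = math.sqrt(rho) * factors[module_of] + math.sqrt(1.0 - rho) * eps

    # planted subtype effects: TNBC is shifted on all n_differential
    # proteins relative to ER+; TN-like carries the same shift (shared
    # direction) on an overlap_fraction subset — the proteins separating
    # TN-like from ER-true that are also ER+/TNBC differential — plus a
    # small TN-like-specific set outside the TNBC signature.
    n_extra = min(spec.n_tnlike_extra, spec.n_proteins - spec.n_differential)
    pick = rng_expr.choice(
        spec.n_proteins, spec.n_differential + n_extra, replace=False
    )
    diff_idx, extra_idx = pick[: spec.n_differential], pick[spec.n_differential:]
    signs = rng_expr.choice([-1.0, 1.0], spec.n_differential)
    n_shared = int(round(spec.overlap_fraction * spec.n_differential))
    shared = np.zeros(spec.n_differential, dtype=bool)
    shared[rng_expr.choice(spec.n_differential, n_shared, replace=False)] = True
    extra_signs = rng_expr.choice([-1.0, 1.0], n_extra)

    is_tnlike = labels == "TN-like"
    is_tnbc = labels == "TNBC"
    z[np.ix_(diff_idx, np.flatnonzero(is_tnbc))] += (
        spec.effect_size * signs[:, None]
    )
    z[np.ix_(diff_idx[shared], np.flatnonzero(is_tnlike))] += (
        spec.effect_size * signs[shared, None]
    )
    if n_extra:
        z[np.ix_(extra_idx, np.flatnonzero(is_tnlike))] += (
            spec.effect_size * extra_signs[:, None]
        )

    # batch assignment (round-robin over a shuffled order) and additive shift
    batch = np.empty(n_samples, dtype=int)
    perm = rng_expr.permutation(n_samples)
    batch[perm] = np.arange(n_samples) % spec.n_batches
    z = z + spec.batch_shift * batch[None, :]

    baseline = rng_expr.normal(
        spec.baseline_log2_mean, spec.baseline_log2_sd, spec.n_proteins
    )
    log2_truth = pd.DataFrame(
        baseline[:, None] + z, index=protein_ids, columns=sample_ids
    )

    # MNAR dropout on the log2 scale, then back to raw intensities
    vals = log2_truth.to_numpy().copy()
    if spec.missing_rate > 0:
        p = _dropout_probs(vals, spec.missing_rate, spec.dropout_steepness)
        vals[rng_miss.random(vals.shape) < p] = np.nan
    raw = pd.DataFrame(
        np.exp2(vals), index=protein_ids, columns=sample_ids
    )

    peptides = pd.Series(
        1 + rng_expr.poisson(3.0, spec.n_proteins), index=protein_ids
    )
    expression = ExpressionMatrix(
        raw, pd.Series("protein", index=protein_ids), peptides
    )

    # miRNAs: noisy linear readouts of protein-module means, random sign
    mods = rng_mirna.integers(0, n_modules, spec.n_mirna)
    mirna_sign = rng_mirna.choice([-1.0, 1.0], spec.n_mirna)
    module_mean = np.vstack(
        [z[module_of == m].mean(axis=0) for m in range(n_modules)]
    )
    mirna_vals = (
        mirna_sign[:, None] * module_mean[mods]
        + 0.5 * rng_mirna.standard_normal((spec.n_mirna, n_samples))
    )
    mirna = pd.DataFrame(
        mirna_vals,
        index=pd.Index([f"miR-{k:03d}" for k in range(spec.n_mirna)]),
        columns=sample_ids,
    )

    # survival: exponential with monthly rate lambda_g = -ln(S5_g)/60
    lam = {g: -math.log(s) / 60.0 for g, s in zip(GROUPS, spec.surv5)}
    t_event = np.array([rng_surv.exponential(1.0 / lam[g]) for g in labels])
    censor = np.where(
        rng_surv.random(n_samples) < spec.censor_rate,
        rng_surv.uniform(0.0, spec.followup_months, n_samples),
        np.inf,
    )
    censor = np.minimum(censor, spec.followup_months)
    time = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)

    annotation = pd.DataFrame(
        {
            "group": labels,
            "batch": batch,
            "dmfs_months": time,
            "event": event,
            "er_status": np.where(is_tnbc, "ER-", "ER+"),
        },
        index=sample_ids,
    )

    return SyntheticCohort(
        expression=expression,
        mirna=mirna,
        annotation=annotation,
        true_labels=pd.Series(labels, index=sample_ids, name="group"),
        true_differential=frozenset(protein_ids[diff_idx]),
        truth_log2=log2_truth,
    )


def _random_tree(n: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Uniform random labelled tree via a Prüfer sequence."""
    if n == 2:
        return [(0, 1)]
    prufer = rng.integers(0, n, n - 2)
    degree = np.ones(n, dtype=int)
    for v in prufer:
        degree[v] += 1
    edges = []
    import heapq

    leaves = [v for v in range(n) if degree[v] == 1]
    heapq.heapify(leaves)
    for v in prufer:
        leaf = heapq.heappop(leaves)
        edges.append((min(leaf, v), max(leaf, v)))
        degree[v] -= 1
        if degree[v] == 1:
            heapq.heappush(leaves, v)
    u, v = leaves
    edges.append((min(u, v), max(u, v)))
    return edges


def generate_tree_gaussian(
    n_vars: int,
    n_samples: int,
    edge_corr: float,
    seed: int | None = None,
) -> tuple[pd.DataFrame, set[tuple[str, str]]]:
    """Sample from a Gaussian Markov tree with correlation ``edge_corr`` on
    each edge (random spanning tree).

    Returns a features x samples DataFrame and the true edge set as
    ``{(feature_i, feature_j), ...}`` with i < j.
    """
    if n_vars < 2:
        raise ValueError("n_vars must be >= 2")
    if abs(edge_corr) >= 1:
        raise ValueError("edge_corr must lie strictly in (-1, 1)")
    rng = np.random.default_rng(seed)
    edges = _random_tree(n_vars, rng)

    children: dict[int, list[int]] = {i: [] for i in range(n_vars)}
    adj: dict[int, list[int]] = {i: [] for i in range(n_vars)}
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    # BFS orientation from vertex 0
    order, seen = [0], {0}
    for v in order:
        for w in adj[v]:
            if w not in seen:
                seen.add(w)
                children[v].append(w)
                order.append(w)

    x = np.empty((n_vars, n_samples))
    x[0] = rng.standard_normal(n_samples)
    r = edge_corr
    for v in order:
        for w in children[v]:
            x[w] = r * x[v] + math.sqrt(1.0 - r * r) * rng.standard_normal(n_samples)

    ids = pd.Index([f"V{i}" for i in range(n_vars)])
    df = pd.DataFrame(x, index=ids, columns=[f"S{j}" for j in range(n_samples)])
    edge_set = {(f"V{a}", f"V{b}") for a, b in edges}
    return df, edge_set
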