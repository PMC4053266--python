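"""Matched multi-table synthetic data with planted cluster structure.

The generator emulates the situation MCIA assumes: several nonnegative
expression-like tables measured on the same samples, each with its own private
feature set and noise, but sharing a sample-level group structure.  Samples
belong to one of ``n_clusters`` groups; within each table a fraction of
features is planted as markers of one cluster and multiplicatively elevated in
that cluster's samples (fold-change semantics).  Intensities are lognormal so
values are strictly positive, matching the NSC nonnegativity precondition.

Ground truth (cluster labels, planted marker ids) is returned alongside the
tables so recovery can be scored without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError
from .tables import RawTable

# Spread of per-feature baseline abundances (log-e sigma).  Kept modest because
# the triplet construction consumes post-normalization (log-scale) intensities,
# whose feature-to-feature dynamic range is compressed; a heavy-tailed baseline
# would let a handful of features monopolize the NSC inertia, which is not the
# regime the method targets.
BASELINE_SIGMA = 0.25


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings; the defaults are the package's reference conditions.

    ``effect_size`` is the multiplicative elevation of a marker in its
    cluster's samples; ``noise_sd`` the sigma of the lognormal measurement
    noise (log-e scale); ``divergent_table_noise`` optional per-table noise
    multipliers for simulating a discordant platform.
    """

    n_samples: int = 30
    n_tables: int = 3
    features_per_table: tuple[int, ...] = (200, 150, 300)
    n_clusters: int = 3
    informative_fraction: float = 0.10
    effect_size: float = 3.0
    noise_sd: float = 0.5
    divergent_table_noise: tuple[float, ...] | None = None
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_clusters > self.n_samples:
            raise InvalidArgumentError("n_clusters cannot exceed n_samples")
        if self.n_clusters < 1 or self.n_samples < 2 or self.n_tables < 1:
            raise InvalidArgumentError("need n_samples >= 2, n_tables >= 1, n_clusters >= 1")
        if len(self.features_per_table) != self.n_tables:
            raise InvalidArgumentError(
                f"features_per_table has {len(self.features_per_table)} entries "
                f"for {self.n_tables} tables"
            )
        if not 0 < self.informative_fraction < 1:
            raise InvalidArgumentError("informative_fraction must be in (0, 1)")
        if self.effect_size <= 0 or self.noise_sd <= 0:
            raise InvalidArgumentError("effect_size and noise_sd must be positive")
        if self.divergent_table_noise is not None and len(self.divergent_table_noise) != self.n_tables:
            raise InvalidArgumentError("divergent_table_noise needs one multiplier per table")


@dataclass
class SyntheticBundle:
    """Generated tables plus the ground truth used to score recovery."""

    tables: list[RawTable]
    cluster_labels: np.ndarray  # per sample, values 0..n_clusters-1
    informative_features: list[dict[int, set[str]]]  # per table: cluster -> feature ids
    spec: SyntheticSpec


def generate_bundle(spec: SyntheticSpec | None = None) -> SyntheticBundle:
    """Generate one bundle; a pure function of ``spec`` (including its seed).

    Samples are assigned to clusters round-robin (deterministic, balanced).
    Per table: baselines are drawn lognormal(1, BASELINE_SIGMA) per feature, noise
    lognormal(0, noise_sd) per entry, and each cluster's disjoint marker set
    (``informative_fraction`` of the table's features) is multiplied by
    ``effect_size`` in that cluster's samples.
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    labels = np.arange(spec.n_samples) % spec.n_clusters
    sample_ids = [f"S{i + 1:03d}" for i in range(spec.n_samples)]
    noise_mult = spec.divergent_table_noise or tuple([1.0] * spec.n_tables)

    tables: list[RawTable] = []
    informative: list[dict[int, set[str]]] = []
    for t in range(spec.n_tables):
        q = spec.features_per_table[t]
        name = f"T{t + 1}"
        feature_ids = [f"{name}_F{j + 1:04d}" for j in range(q)]
        baseline = rng.lognormal(mean=1.0, sigma=BASELINE_SIGMA, size=q)
        noise = rng.lognormal(mean=0.0, sigma=spec.noise_sd * noise_mult[t], size=(q, spec.n_samples))
        values = baseline[:, None] * noise

        n_inf = max(1, int(round(spec.informative_fraction * q)))
        if n_inf * spec.n_clusters > q:
            raise InvalidArgumentError(
                f"table {name}: {n_inf} markers x {spec.n_clusters} clusters exceed {q} features"
            )
        chosen = rng.choice(q, size=n_inf * spec.n_clusters, replace=False)
        per_cluster: dict[int, set[str]] = {}
        for c in range(spec.n_clusters):
            rows = chosen[c * n_inf:(c + 1) * n_inf]
            per_cluster[c] = {feature_ids[j] for j in rows}
            cols = np.flatnonzero(labels == c)
            values[np.ix_(rows, cols)] *= spec.effect_size
        informative.append(per_cluster)
        tables.append(
            RawTable(
                name=name,
                feature_ids=feature_ids,
                sample_ids=sample_ids,
                values=values,
                missing_mask=np.zeros_like(values, dtype=bool),
            )
        )
    return SyntheticBundle(
        tables=tables, cluster_labels=labels, informative_features=informative, spec=spec
    )


def inject_missingness(bundle: SyntheticBundle, rate: float, seed: int) -> SyntheticBundle:
    """Mask each entry independently with probability ``rate`` (per-seed deterministic)."""
    if not 0 <= rate < 1:
        raise InvalidArgumentError(f"missingness rate must be in [0, 1), got {rate}")
    if rate == 0:
        return bundle
    rng = np.random.default_rng(seed)
    masked = []
    for t in bundle.tables:
        mask = rng.random(t.values.shape) < rate
        masked.append(
            RawTable(
                name=t.name,
                feature_ids=list(t.feature_ids),
                sample_ids=list(t.sample_ids),
                values=t.values.copy(),
                missing_mask=t.missing_mask | mask,
            )
        )
    return SyntheticBundle(
        tables=masked,
        cluster_labels=bundle.cluster_labels.copy(),
        informative_features=[{c: set(v) for c, v in m.items()} for m in bundle.informative_features],
        spec=bundle.spec,
    )
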