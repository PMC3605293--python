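"""Expression quantification and the ageing analyses.

Transcript levels are quantified as RPKM (reads per kilobase of transcript
per million mapped reads) from unique-mapping counts.  Sample structure is
characterized by Spearman correlation and PCA on log-transformed RPKM.
Differentially expressed gene (DEG) lists are ingested (DEG calling itself
is upstream); the module tests cross-species DEG overlap with an exact
binomial test and compares per-strain fold changes with a paired Wilcoxon
test, optionally after rescaling the longer-lived strain's fold changes to a
common chronological span under a linear-change-in-level assumption.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .formats_io import ConfigError, ExpressionMatrix

LOG_OFFSET = 1.0  # log10(rpkm + 1) before correlation/PCA


@dataclass(frozen=True)
class DEGRecord:
    gene: str
    tissue: str
    fc_per_strain: Mapping[str, float]  # old/young level ratio, > 0
    p_value: float = float("nan")
    direction: str = "up"

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ConfigError(f"direction must be 'up' or 'down', got {self.direction!r}")
        for strain, fc in self.fc_per_strain.items():
            if fc <= 0:
                raise ConfigError(f"{self.gene}: fold change for {strain} must be > 0")


@dataclass(frozen=True)
class TimeSpans:
    """Weeks between young and old sampling per strain (e.g. GRZ 14-5=9)."""

    spans: Mapping[str, float]

    def __post_init__(self) -> None:
        for strain, span in self.spans.items():
            if span <= 0:
                raise ConfigError(f"span for {strain} must be > 0")

    def __getitem__(self, strain: str) -> float:
        return self.spans[strain]


def rpkm(matrix: ExpressionMatrix) -> pd.DataFrame:
    """count / (length_kb x total_millions), per gene and sample."""
    totals = matrix.sample_totals
    if (totals <= 0).any():
        bad = totals[totals <= 0].index.tolist()
        raise ConfigError(f"zero mapped-read total for samples {bad}")
    length_kb = matrix.gene_lengths / 1_000.0
    total_m = totals / 1_000_000.0
    return matrix.counts.div(length_kb, axis=0).div(total_m, axis=1)


@dataclass
class SampleStructure:
    correlation: pd.DataFrame
    dendrogram_order: list[str]
    components: np.ndarray  # samples x components
    variance_pct: np.ndarray
    dropped_genes: list[str] = field(default_factory=list)


def sample_structure(rpkm_matrix: pd.DataFrame) -> SampleStructure:
    """Spearman correlation structure and PCA of log-transformed RPKM.

    RPKM values are log10(x + 1)-transformed; constant genes are dropped
    with a warning.  The correlation matrix is symmetric with unit diagonal;
    samples are ordered by average-linkage clustering on 1 - correlation.
    PCA is run on centered per-sample profiles; variance percentages are
    descending and sum to 100.
    """
    if rpkm_matrix.shape[1] < 2:
        raise ConfigError("need at least two samples")
    log_vals = np.log10(rpkm_matrix + LOG_OFFSET)
    constant = log_vals.index[log_vals.nunique(axis=1) == 1]
    if len(constant):
        warnings.warn(f"dropping {len(constant)} constant gene rows", stacklevel=2)
        log_vals = log_vals.drop(index=constant)

    rho, _ = stats.spearmanr(log_vals.to_numpy())
    rho = np.atleast_2d(rho)
    corr = pd.DataFrame(rho, index=rpkm_matrix.columns, columns=rpkm_matrix.columns)

    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = [rpkm_matrix.columns[i] for i in hierarchy.leaves_list(linkage)]

    profiles = log_vals.to_numpy().T  # samples x genes
    centered = profiles - profiles.mean(axis=0, keepdims=True)
    _, singular, vt = np.linalg.svd(centered, full_matrices=False)
    variances = singular**2
    total = variances.sum()
    variance_pct = 100.0 * variances / total if total > 0 else np.zeros_like(variances)
    components = centered @ vt.T
    return SampleStructure(
        correlation=corr,
        dendrogram_order=order,
        components=components,
        variance_pct=variance_pct,
        dropped_genes=list(constant),
    )


@dataclass
class OverlapResult:
    k: int
    n: int
    null_p: float
    p_value: float
    excluded_genes: list[str] = field(default_factory=list)


def overlap_binomial_test(
    degs_a: Sequence[DEGRecord],
    degs_b: Sequence[DEGRecord],
    universe_b: int,
    direction_factor: float = 0.5,
    universe_genes: set[str] | None = None,
) -> OverlapResult:
    """Exact binomial test for directional DEG overlap between species.

    k counts genes from ``degs_a`` found in ``degs_b`` with the same
    direction; the null probability is (|degs_b| / universe_b) x
    ``direction_factor`` (a random gene matches direction half the time by
    default).  P(X >= k) is the upper-tail exact binomial.  Genes of
    ``degs_a`` absent from the universe mapping are excluded and reported.
    """
    if not degs_b or universe_b < len(degs_b):
        raise ConfigError("require universe_b >= |degs_b| > 0")
    excluded: list[str] = []
    usable: list[DEGRecord] = []
    for rec in degs_a:
        if universe_genes is not None and rec.gene not in universe_genes:
            excluded.append(rec.gene)
        else:
            usable.append(rec)
    direction_b = {rec.gene: rec.direction for rec in degs_b}
    k = sum(1 for rec in usable if direction_b.get(rec.gene) == rec.direction)
    n = len(usable)
    null_p = (len(degs_b) / universe_b) * direction_factor
    p_value = float(stats.binom.sf(k - 1, n, null_p)) if n else 1.0
    return OverlapResult(k=k, n=n, null_p=null_p, p_value=p_value, excluded_genes=excluded)


def time_normalize_fc(
    fc: float,
    span_source: float,
    span_target: float,
    mode: str = "linear_level",
    gene: str = "?",
) -> float:
    """Rescale an old/young fold change to a different chronological span.

    ``linear_level`` assumes transcript levels change linearly in time, so
    the level offset (fc - 1) scales with the span ratio; ``log_linear``
    scales log(fc) instead.  The linear mode errors when the rescaled ratio
    would be non-positive (only possible when extrapolating to a longer
    span with fc < 1).
    """
    if fc <= 0 or span_source <= 0 or span_target <= 0:
        raise ConfigError("fc and spans must be > 0")
    ratio = span_target / span_source
    if mode == "linear_level":
        out = 1.0 + (fc - 1.0) * ratio
        if out <= 0:
            raise ConfigError(f"gene {gene}: normalized fold change {out:.3g} <= 0")
        return out
    if mode == "log_linear":
        return float(np.exp(np.log(fc) * ratio))
    raise ConfigError(f"unknown mode {mode!r}")


@dataclass
class StrainComparison:
    p_all: float | None
    p_up: float | None
    p_down: float | None
    n_all: int
    normalized: bool
    mode: str


def _wilcoxon(log_a: np.ndarray, log_b: np.ndarray) -> float | None:
    if len(log_a) < 2:
        return None
    diff = log_a - log_b
    if np.allclose(diff, 0):
        return 1.0
    method = "exact" if len(diff) <= 25 else "approx"
    res = stats.wilcoxon(log_a, log_b, method=method, correction=(method == "approx"))
    return float(res.pvalue)


def compare_strain_fc(
    degs: Sequence[DEGRecord],
    spans: TimeSpans,
    normalize: bool = True,
    mode: str = "linear_level",
) -> StrainComparison:
    """Paired Wilcoxon comparison of per-strain fold changes.

    Every DEG must carry a fold change for both strains.  With
    ``normalize``, the longer-span strain's fold changes are mapped to the
    shorter span through :func:`time_normalize_fc` before testing.  The test
    runs on log-transformed ratios — exact distribution for n <= 25, normal
    approximation with continuity correction otherwise — over all genes and
    separately over the up- and downregulated subsets.
    """
    strains = sorted(spans.spans, key=lambda s: spans[s])
    if len(strains) != 2:
        raise ConfigError("exactly two strains required")
    short, long_ = strains

    def fc_pair(rec: DEGRecord) -> tuple[float, float]:
        fc_short = rec.fc_per_strain[short]
        fc_long = rec.fc_per_strain[long_]
        if normalize:
            fc_long = time_normalize_fc(fc_long, spans[long_], spans[short], mode, rec.gene)
        return fc_short, fc_long

    pairs = [(rec.direction, *fc_pair(rec)) for rec in degs]
    log_s = np.log([p[1] for p in pairs])
    log_l = np.log([p[2] for p in pairs])
    directions = np.array([p[0] for p in pairs])
    up = directions == "up"
    down = ~up
    return StrainComparison(
        p_all=_wilcoxon(log_s, log_l),
        p_up=_wilcoxon(log_s[up], log_l[up]),
        p_down=_wilcoxon(log_s[down], log_l[down]),
        n_all=len(pairs),
        normalized=normalize,
        mode=mode,
    )


def pooled_count_test(
    counts_a: np.ndarray, counts_b: np.ndarray, totals_a: float, totals_b: float
) -> np.ndarray:
    """Per-gene two-condition exact binomial test on pooled counts.

    A convenience smoke test for synthetic data: under the null a read from
    the pooled pair lands in condition A with probability
    totals_a / (totals_a + totals_b).  This is NOT equivalent to a
    dispersion-aware negative-binomial DEG caller and is not meant to
    reproduce one.
    """
    counts_a = np.asarray(counts_a)
    counts_b = np.asarray(counts_b)
    p_null = totals_a / (totals_a + totals_b)
    out = np.ones(len(counts_a))
    for i, (a, b) in enumerate(zip(counts_a, counts_b)):
        n = int(a + b)
        if n == 0:
            continue
        out[i] = float(stats.binomtest(int(a), n, p_null).pvalue)
    return out
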