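"""Diamond-motif counting and the degree-proportional null-model test.

A diamond-shaped module is an unordered pair of distinct fungi linked to
the same mycoheterotrophic plant AND the same autotrophic plant (4 nodes,
4 edges). With shared-partner count matrices P = M^T M (mycoheterotrophs)
and Q = A^T A (autotrophs) over the aligned fungal axis, the number of
diamonds is

    sum over fungus pairs f1 < f2 of P[f1, f2] * Q[f1, f2],

which equals the exhaustive enumeration of (MH plant, autotroph plant,
fungus pair) quadruples.

Observed counts are compared against Bernoulli null networks in which the
probability of each plant-fungus link is the arithmetic mean of the
plant's and the fungus's fill fractions (the classic degree-proportional
bipartite null), with the two guild blocks randomised separately and
recombined before the module search. Overrepresentation is declared when
the observed count exceeds the 97.5th percentile of the null counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import NullModelError, ValidationError
from .networks import TripartiteNetwork, restrict_to_shared_fungi


def count_diamond_modules(net: TripartiteNetwork) -> int:
    """Number of diamond-shaped modules in the tripartite network."""
    m = net.mh.to_numpy(dtype=np.int64)
    a = net.auto.to_numpy(dtype=np.int64)
    p = m.T @ m
    q = a.T @ a
    total = int((p * q).sum() - (np.diag(p) * np.diag(q)).sum()) // 2
    return total


def count_diamonds_bruteforce(net: TripartiteNetwork) -> int:
    """Exhaustive quadruple enumeration; O(m a f^2) reference oracle."""
    m = net.mh.to_numpy(dtype=bool)
    a = net.auto.to_numpy(dtype=bool)
    f = m.shape[1]
    total = 0
    for f1 in range(f):
        for f2 in range(f1 + 1, f):
            for i in range(m.shape[0]):
                if not (m[i, f1] and m[i, f2]):
                    continue
                for j in range(a.shape[0]):
                    if a[j, f1] and a[j, f2]:
                        total += 1
    return total


@dataclass(frozen=True)
class NullModelSpec:
    """Cell probabilities for the degree-proportional Bernoulli null of one
    incidence block: p_ij = (k_i/C + k_j/R) / 2, which conserves the block's
    expected link total exactly (sum_ij p_ij = number of links)."""

    probs: np.ndarray
    row_degrees: np.ndarray
    col_degrees: np.ndarray
    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]

    @property
    def shape(self) -> tuple[int, int]:
        return self.probs.shape

    @property
    def n_links(self) -> int:
        return int(self.row_degrees.sum())


def null_probabilities(incidence: pd.DataFrame) -> NullModelSpec:
    """Degree-proportional null probabilities of one binary block."""
    if incidence.size == 0:
        raise ValidationError("cannot build a null model for an empty block")
    arr = incidence.to_numpy(dtype=np.int64)
    if not np.isin(arr, (0, 1)).all():
        raise ValidationError("null model requires a binary incidence block")
    r, c = arr.shape
    k_row = arr.sum(axis=1)
    k_col = arr.sum(axis=0)
    probs = 0.5 * (k_row[:, None] / c + k_col[None, :] / r)
    return NullModelSpec(
        probs=probs,
        row_degrees=k_row,
        col_degrees=k_col,
        row_ids=tuple(map(str, incidence.index)),
        col_ids=tuple(map(str, incidence.columns)),
    )


def sample_null_network(
    spec: NullModelSpec,
    rng: np.random.Generator,
    max_retries: int = 1000,
    forbid_empty: str = "rows",
) -> pd.DataFrame:
    """One Bernoulli(p_ij) draw from a null spec.

    An observed network cannot contain a plant with zero fungi, so by
    default draws with an empty row are rejected and the whole matrix
    redrawn (up to ``max_retries`` times) rather than patched cell-wise.
    Column (fungus) emptiness is allowed by default because empirical guild
    blocks themselves carry zero-degree fungal columns (a fungus used only
    by the other guild), which makes a jointly non-empty draw both
    unrepresentative and, for study-shaped blocks, astronomically rare.
    ``forbid_empty`` is one of "rows", "rows+cols", "none".
    """
    if forbid_empty not in ("rows", "rows+cols", "none"):
        raise ValidationError("forbid_empty must be 'rows', 'rows+cols' or 'none'")
    for _ in range(max_retries):
        draw = (rng.random(spec.probs.shape) < spec.probs).astype(np.int8)
        if forbid_empty == "none":
            break
        if draw.any(axis=1).all() and (
            forbid_empty == "rows" or draw.any(axis=0).all()
        ):
            break
    else:
        raise NullModelError(
            f"no draw without empty rows/columns in {max_retries} attempts"
        )
    return pd.DataFrame(draw, index=list(spec.row_ids), columns=list(spec.col_ids))


def randomize_tripartite(
    net: TripartiteNetwork,
    rng: np.random.Generator,
    specs: tuple[NullModelSpec, NullModelSpec] | None = None,
) -> TripartiteNetwork:
    """Randomise the two guild blocks independently and recombine them.

    Each block gets its own degree-proportional spec (computed from the
    empirical block unless precomputed specs are passed); the fungal column
    alignment is preserved.
    """
    if specs is None:
        specs = (null_probabilities(net.mh), null_probabilities(net.auto))
    mh = sample_null_network(specs[0], rng)
    auto = sample_null_network(specs[1], rng)
    return TripartiteNetwork(mh=mh, auto=auto)


@dataclass(frozen=True)
class DiamondMotifResult:
    """Observed diamond count against its null distribution.

    z is None when the null counts are constant (SD 0); the empirical p uses
    the +1/+1 convention so it is never exactly 0; ``overrepresented`` is
    governed by the 95% percentile interval of null counts (observed above
    the 97.5th percentile), which takes precedence over z when they
    disagree.
    """

    observed: int
    null_counts: tuple[int, ...]
    scope: str
    null_mean: float = field(init=False)
    null_sd: float = field(init=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.null_counts, dtype=float)
        object.__setattr__(self, "null_mean", float(counts.mean()))
        object.__setattr__(self, "null_sd", float(counts.std(ddof=0)))

    @property
    def n_null(self) -> int:
        return len(self.null_counts)

    @property
    def z(self) -> float | None:
        if self.null_sd == 0.0:
            return None
        return (self.observed - self.null_mean) / self.null_sd

    @property
    def p_empirical(self) -> float:
        counts = np.asarray(self.null_counts)
        return (1.0 + int((counts >= self.observed).sum())) / (1.0 + self.n_null)

    @property
    def ci_low(self) -> float:
        return float(np.percentile(self.null_counts, 2.5))

    @property
    def ci_high(self) -> float:
        return float(np.percentile(self.null_counts, 97.5))

    @property
    def overrepresented(self) -> bool:
        return self.observed > self.ci_high

    @property
    def underrepresented(self) -> bool:
        return self.observed < self.ci_low

    def to_dict(self) -> dict:
        return {
            "scope": self.scope,
            "observed": self.observed,
            "n_null": self.n_null,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "z": self.z,
            "p_empirical": self.p_empirical,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "overrepresented": self.overrepresented,
        }

    def summary(self) -> str:
        z = "undefined (constant null)" if self.z is None else f"{self.z:.3f}"
        flag = (
            "OVERREPRESENTED"
            if self.overrepresented
            else ("underrepresented" if self.underrepresented else "within null 95% interval")
        )
        return "\n".join(
            [
                f"Diamond-motif null-model test (scope: {self.scope} fungi)",
                f"  observed modules     : {self.observed}",
                f"  null mean +- SD      : {self.null_mean:.2f} +- {self.null_sd:.2f}"
                f"  ({self.n_null} null networks)",
                f"  null 95% interval    : [{self.ci_low:.1f}, {self.ci_high:.1f}]",
                f"  z-score              : {z}",
                f"  empirical p          : {self.p_empirical:.4g}",
                f"  verdict              : {flag}",
            ]
        )


class DiamondMotifTest:
    """Model object for the diamond-motif overrepresentation test.

    Parameters
    ----------
    net:
        The empirical tripartite network.
    scope:
        "all" counts modules over every fungus in the network; "shared"
        first restricts the EMPIRICAL network to fungi present in both
        guilds, and builds null probabilities from the restricted blocks.

    ``fit`` draws the null ensemble and returns a
    :class:`DiamondMotifResult`.
    """

    def __init__(self, net: TripartiteNetwork, scope: str = "all"):
        if scope not in ("all", "shared"):
            raise ValidationError("scope must be 'all' or 'shared'")
        self.scope = scope
        self.net = restrict_to_shared_fungi(net) if scope == "shared" else net
        self.specs = (null_probabilities(self.net.mh), null_probabilities(self.net.auto))
        self.observed = count_diamond_modules(self.net)

    def fit(
        self,
        n_null: int = 1000,
        rng: np.random.Generator | int | None = None,
    ) -> DiamondMotifResult:
        if n_null < 2:
            raise ValidationError("n_null must be >= 2")
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        counts = np.empty(n_null, dtype=np.int64)
        for k in range(n_null):
            counts[k] = count_diamond_modules(
                randomize_tripartite(self.net, rng, specs=self.specs)
            )
        return DiamondMotifResult(
            observed=self.observed,
            null_counts=tuple(int(c) for c in counts),
            scope=self.scope,
        )


def motif_null_test(
    net: TripartiteNetwork,
    scope: str = "all",
    n_null: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> DiamondMotifResult:
    """Functional wrapper: build a :class:`DiamondMotifTest` and fit it."""
    return DiamondMotifTest(net, scope=scope).fit(n_null=n_null, rng=rng)
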