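"""Conditional-dependence screen of miRNA–target interactions.

Given the complexes flagged as dysregulated, this stage asks which
miRNA–target interactions *depend on* a complex member protein: for each
triplet (miRNA x, validated target y, complex protein z) it compares the
conditional mutual information I(X;Y|Z) with the unconditional I(X;Y).  The
statistic is the CMI itself; its null distribution is obtained by permuting
the protein's expression profile, which breaks any protein dependence while
keeping the miRNA–target relationship intact.  The alternative statistic
|CMI − MI| (the change relative to the unconditional association) is
available but folds the discrepancy between the 2-D and 3-D estimators into
the statistic, which costs power.
Per-complex evidence is combined across its triplets with Fisher's method
(−2 Σ ln p ~ χ² with 2k degrees of freedom).

The protein–target dependency network collects significant triplets as
(protein, target, miRNA) edges.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import ConditionData, InteractionSet
from .mi_estimation import (
    MIEstimatorConfig,
    ProfileKDE,
    _cmi_from_kdes,
    _mi_from_kdes,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DownstreamConfig",
    "DependencyResult",
    "ComplexDependencySummary",
    "interaction_dependency",
    "fisher_combine",
    "screen_downstream",
    "dependency_network",
    "dependencies_table",
    "summaries_table",
]


def _hash32(text: str) -> int:
    digest = hashlib.blake2s(text.encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") & 0x7FFFFFFF


@dataclass(frozen=True)
class DownstreamConfig:
    """Settings of the conditional-dependence screen."""

    n_permutations: int = 1000
    seed: int = 0
    statistic: str = "cmi"  # permutation statistic; "delta" uses |CMI - MI|
    exclude_self_targets: bool = True

    def __post_init__(self) -> None:
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if self.statistic not in ("delta", "cmi"):
            raise ValueError(f"unknown statistic {self.statistic!r}")


@dataclass(frozen=True)
class DependencyResult:
    """Permutation test of one (miRNA, target, protein) triplet."""

    mirna_id: str
    target_id: str
    protein_id: str
    cmi: float
    mi: float
    delta_stat: float
    p_value: float
    n_permutations: int
    testable: bool = True
    complex_ids: tuple = ()


@dataclass(frozen=True)
class ComplexDependencySummary:
    """Fisher-combined downstream evidence for one complex."""

    set_id: str
    k: int
    fisher_statistic: float
    combined_p: float
    testable: bool = True


def interaction_dependency(
    mirna_profile,
    target_profile,
    protein_profile,
    n_permutations: int = 1000,
    seed: int | np.random.Generator = 0,
    config: MIEstimatorConfig | None = None,
    statistic: str = "cmi",
    mirna_id: str = "",
    target_id: str = "",
    protein_id: str = "",
) -> DependencyResult:
    """Test whether a miRNA–target interaction depends on a protein.

    The observed statistic (the CMI by default, |CMI − MI| with
    ``statistic="delta"``) is compared against ``n_permutations``
    recomputations with the protein profile randomly permuted; the p-value
    uses the add-one estimator.  Constant profiles make the triplet
    untestable (flagged, p = NaN).
    """
    config = config or MIEstimatorConfig()
    if statistic not in ("delta", "cmi"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    x = np.asarray(mirna_profile, dtype=float)
    y = np.asarray(target_profile, dtype=float)
    z = np.asarray(protein_profile, dtype=float)
    if not (x.size == y.size == z.size):
        raise ValueError("profile lengths differ")

    g = config.cmi_grid_points_per_axis
    kx = ProfileKDE(x, config, grid_points=g, dim=3)
    ky = ProfileKDE(y, config, grid_points=g, dim=3)
    kz = ProfileKDE(z, config, grid_points=g, dim=3)
    if kx.constant or ky.constant or kz.constant:
        logger.warning("constant profile in triplet (%s, %s, %s): untestable",
                       mirna_id, target_id, protein_id)
        return DependencyResult(mirna_id, target_id, protein_id,
                                cmi=0.0, mi=0.0, delta_stat=0.0,
                                p_value=float("nan"),
                                n_permutations=n_permutations, testable=False)

    mi = _mi_from_kdes(ProfileKDE(x, config), ProfileKDE(y, config), config)
    n = x.size
    pair_xy = (kx.K[:, None, :] * ky.K[None, :, :]).reshape(g * g, n)

    def stat_for(Kz: np.ndarray) -> tuple[float, float]:
        cmi = _cmi_from_kdes(kx, ky, kz, config, pair_xy=pair_xy, Kz=Kz)
        return cmi, (abs(cmi - mi) if statistic == "delta" else cmi)

    cmi_obs, s_obs = stat_for(kz.K)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        _, s_perm = stat_for(kz.K[:, perm])
        if s_perm >= s_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return DependencyResult(mirna_id, target_id, protein_id,
                            cmi=cmi_obs, mi=mi, delta_stat=s_obs, p_value=p,
                            n_permutations=n_permutations)


def fisher_combine(p_values) -> tuple[float, float]:
    """Fisher's method: statistic −2 Σ ln p ~ χ²(2k); returns (stat, p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size < 1:
        raise ValueError("fisher_combine requires at least one p-value")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    statistic = float(-2.0 * np.log(p).sum())
    combined = float(stats.chi2.sf(statistic, df=2 * p.size))
    return statistic, max(combined, np.finfo(float).tiny)


def screen_downstream(
    selected_complexes,
    interactions: InteractionSet,
    cond: ConditionData,
    config: DownstreamConfig | None = None,
    mi_config: MIEstimatorConfig | None = None,
):
    """Screen all testable triplets of the selected complexes.

    For every member protein of each selected complex and every interaction
    edge (miRNA, target) with both profiles measured — excluding targets
    belonging to the complex under test unless configured otherwise — one
    permutation test is run.  A triplet shared by several complexes is
    computed once and attributed to all of them.  Per complex, its triplets'
    p-values are Fisher-combined.

    ``selected_complexes`` accepts the module results of the significance
    screen or plain module definitions (anything with ``set_id`` and member
    proteins).  Returns ``(dependency_results, complex_summaries)``.
    """
    config = config or DownstreamConfig()
    mi_config = mi_config or MIEstimatorConfig()
    if not selected_complexes:
        raise ValueError("no complexes selected for the downstream screen")
    if len(interactions) == 0:
        raise ValueError("interaction set is empty")

    def members(item) -> tuple:
        return item.entropy.proteins if hasattr(item, "entropy") else item.proteins

    edges = sorted(
        (m, t) for m, t in interactions.edges
        if m in cond.mirna and t in cond.mrna
    )
    # assemble unique triplets and which complexes claim them
    triplet_complexes: dict = {}
    complex_triplets: dict = {}
    for item in selected_complexes:
        set_id = item.set_id
        proteins = members(item)
        in_complex = set(proteins)
        keys = []
        for z in proteins:
            if z not in cond.mrna:
                continue
            for m, t in edges:
                if config.exclude_self_targets and t in in_complex:
                    continue
                if t == z:
                    continue
                key = (m, t, z)
                triplet_complexes.setdefault(key, []).append(set_id)
                keys.append(key)
        complex_triplets[set_id] = keys

    results: dict = {}
    for key in sorted(triplet_complexes):
        m, t, z = key
        rng = np.random.default_rng(
            [config.seed, _hash32(m), _hash32(t), _hash32(z)]
        )
        res = interaction_dependency(
            cond.mirna.profile(m), cond.mrna.profile(t), cond.mrna.profile(z),
            n_permutations=config.n_permutations, seed=rng,
            config=mi_config, statistic=config.statistic,
            mirna_id=m, target_id=t, protein_id=z,
        )
        results[key] = DependencyResult(
            **{**res.__dict__, "complex_ids": tuple(sorted(set(triplet_complexes[key])))}
        )

    summaries = []
    for item in selected_complexes:
        set_id = item.set_id
        ps = [results[k].p_value for k in complex_triplets[set_id]
              if results[k].testable]
        if not ps:
            logger.warning("complex %r has no testable triplets", set_id)
            summaries.append(ComplexDependencySummary(set_id, 0, 0.0,
                                                      float("nan"), testable=False))
            continue
        statistic, combined = fisher_combine(ps)
        summaries.append(ComplexDependencySummary(set_id, len(ps), statistic, combined))

    dependency_list = [results[k] for k in sorted(results)]
    dependency_list.sort(key=lambda r: (np.nan_to_num(r.p_value, nan=2.0),
                                        r.mirna_id, r.target_id, r.protein_id))
    summaries.sort(key=lambda s: (np.nan_to_num(s.combined_p, nan=2.0), s.set_id))
    return dependency_list, summaries


def dependency_network(results, alpha: float) -> pd.DataFrame:
    """Protein→target dependency edges at significance level ``alpha``.

    One edge (protein, target, miRNA, p) per testable triplet with
    p ≤ alpha; two proteins are thereby connected whenever a miRNA–target
    interaction of one depends on the other.
    """
    if not (0 < alpha < 1 or alpha == 1.0):
        raise ValueError("alpha must lie in (0, 1]")
    rows = [
        {"protein_id": r.protein_id, "target_id": r.target_id,
         "mirna_id": r.mirna_id, "p_value": r.p_value}
        for r in results
        if r.testable and r.p_value <= alpha
    ]
    df = pd.DataFrame(rows, columns=["protein_id", "target_id", "mirna_id", "p_value"])
    return df.sort_values(["p_value", "protein_id", "target_id", "mirna_id"],
                          ignore_index=True)


def dependencies_table(results) -> pd.DataFrame:
    rows = [
        {
            "mirna_id": r.mirna_id,
            "target_id": r.target_id,
            "protein_id": r.protein_id,
            "cmi": r.cmi,
            "mi": r.mi,
            "statistic": r.delta_stat,
            "p_value": r.p_value,
            "n_permutations": r.n_permutations,
            "testable": r.testable,
            "complex_ids": ",".join(r.complex_ids),
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def summaries_table(summaries) -> pd.DataFrame:
    rows = [
        {
            "set_id": s.set_id,
            "k": s.k,
            "fisher_statistic": s.fisher_statistic,
            "combined_p": s.combined_p,
            "testable": s.testable,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows)
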