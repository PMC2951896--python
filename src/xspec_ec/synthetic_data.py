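"""Two-species tissue-expression simulator with known conservation truth.

The generative model is a latent-module factor model on the log scale:
m module activity profiles are drawn per tissue, each gene loads on the
modules, and intensity-scale expression is ``intensity_scale *
exp(loading . activity + noise)`` — strictly positive, right-skewed
values with multiplicative noise, resembling summarized microarray
output.  Module structure gives the reference set genuine co-expression
(without it, PCM rows would be pure noise and co-expression methods would
have nothing to measure).

Cross-species structure:

* the first ``n_common`` tissue columns of the two species correspond;
  species B's activities there equal species A's plus
  ``Normal(0, tissue_evolution_sd)`` (tissues themselves evolve);
  remaining columns are independent species-specific tissues;
* a fraction ``p_cons`` of genes is conserved: their module loadings are
  identical in both species.  Diverged genes get
  ``(1 - d) * loading_A + d * fresh`` with ``d = divergence_d``
  (``d = 1`` replaces the program outright);
* ``divergence_scope="noncommon"`` confines the divergence to species B's
  non-common tissues (common-tissue expression still uses the conserved
  program) — the regime where corresponding-tissue panels hide divergence
  that the full data can see.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_io import ExpressionMatrix, PairedExpression, ValidationError
from .tissue_ec import ECResult

__all__ = ["SimulationConfig", "SimTruth", "simulate_paired_expression", "recovery_score"]


@dataclass
class SimulationConfig:
    """Simulator parameters.

    Defaults describe the standard study condition used throughout the
    test-bed: 500 ortholog pairs over 30 / 24 tissues with 20
    corresponding, 8 latent modules, half the genes conserved, full
    program replacement for diverged genes, mild tissue evolution and
    moderate multiplicative noise.
    """

    k: int = 500
    t_A: int = 30
    t_B: int = 24
    n_common: int = 20
    m: int = 8
    p_cons: float = 0.5
    divergence_d: float = 1.0
    tissue_evolution_sd: float = 0.2
    noise_sd: float = 0.3
    intensity_scale: float = 1000.0
    seed: int = 7
    divergence_scope: str = "global"

    def __post_init__(self) -> None:
        if self.k < 1 or self.m < 1:
            raise ValidationError("k and m must be >= 1")
        if self.t_A < 1 or self.t_B < 1:
            raise ValidationError("tissue counts must be >= 1")
        if not 0 <= self.n_common <= min(self.t_A, self.t_B):
            raise ValidationError("n_common must be <= min(t_A, t_B)")
        if not 0 <= self.p_cons <= 1 or not 0 <= self.divergence_d <= 1:
            raise ValidationError("p_cons and divergence_d must lie in [0, 1]")
        if self.tissue_evolution_sd < 0 or self.noise_sd < 0:
            raise ValidationError("standard deviations must be nonnegative")
        if self.intensity_scale <= 0:
            raise ValidationError("intensity_scale must be positive")
        if self.divergence_scope not in ("global", "noncommon"):
            raise ValidationError("divergence_scope must be 'global' or 'noncommon'")


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated dataset."""

    conserved: np.ndarray
    loading_A: np.ndarray
    loading_B: np.ndarray
    module_activity_A: np.ndarray
    module_activity_B: np.ndarray
    config: SimulationConfig = field(default=None)  # type: ignore[assignment]


def simulate_paired_expression(
    config: SimulationConfig,
) -> tuple[PairedExpression, SimTruth]:
    """Draw one paired dataset plus its conservation truth (fully seeded)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    act_A = rng.standard_normal((cfg.m, cfg.t_A))
    act_B = np.empty((cfg.m, cfg.t_B))
    act_B[:, : cfg.n_common] = act_A[:, : cfg.n_common] + rng.normal(
        0.0, cfg.tissue_evolution_sd, size=(cfg.m, cfg.n_common)
    )
    if cfg.t_B > cfg.n_common:
        act_B[:, cfg.n_common :] = rng.standard_normal((cfg.m, cfg.t_B - cfg.n_common))

    loading_A = rng.standard_normal((cfg.k, cfg.m))
    n_cons = int(round(cfg.p_cons * cfg.k))
    conserved = np.zeros(cfg.k, dtype=bool)
    conserved[rng.permutation(cfg.k)[:n_cons]] = True
    fresh = rng.standard_normal((cfg.k, cfg.m))
    loading_B = loading_A.copy()
    div = ~conserved
    loading_B[div] = (1.0 - cfg.divergence_d) * loading_A[div] + cfg.divergence_d * fresh[div]

    noise_A = rng.normal(0.0, cfg.noise_sd, size=(cfg.k, cfg.t_A))
    noise_B = rng.normal(0.0, cfg.noise_sd, size=(cfg.k, cfg.t_B))

    log_A = loading_A @ act_A + noise_A
    log_B = loading_B @ act_B + noise_B
    if cfg.divergence_scope == "noncommon" and cfg.n_common > 0:
        # common tissues keep the ancestral (species A) program for every gene
        log_B[:, : cfg.n_common] = (loading_A @ act_B[:, : cfg.n_common]) + noise_B[
            :, : cfg.n_common
        ]

    values_A = cfg.intensity_scale * np.exp(log_A)
    values_B = cfg.intensity_scale * np.exp(log_B)

    gene_ids = [f"g{i + 1:04d}" for i in range(cfg.k)]
    tissues_A = [f"ct{j + 1:02d}" for j in range(cfg.n_common)] + [
        f"sa{j + 1:02d}" for j in range(cfg.t_A - cfg.n_common)
    ]
    tissues_B = [f"ct{j + 1:02d}" for j in range(cfg.n_common)] + [
        f"sb{j + 1:02d}" for j in range(cfg.t_B - cfg.n_common)
    ]
    paired = PairedExpression(
        ExpressionMatrix(gene_ids, tissues_A, values_A),
        ExpressionMatrix(list(gene_ids), tissues_B, values_B),
    )
    truth = SimTruth(
        conserved=conserved,
        loading_A=loading_A,
        loading_B=loading_B,
        module_activity_A=act_A,
        module_activity_B=act_B,
        config=cfg,
    )
    return paired, truth


def recovery_score(ec: ECResult, truth: SimTruth) -> float:
    """AUC of the EC vector as a classifier of the conservation label.

    The probability that a uniformly random (conserved, diverged) pair of
    valid genes is ordered correctly by EC; ties count one half.
    """
    if ec.ec is None:
        raise ValidationError("result carries no EC vector")
    if ec.k != truth.conserved.shape[0]:
        raise ValidationError("EC and truth lengths differ")
    mask = ec.valid & np.isfinite(ec.ec)
    pos = ec.ec[mask & truth.conserved]
    neg = ec.ec[mask & ~truth.conserved]
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("need at least one valid EC in each class")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    rank_sum_pos = ranks[: pos.size].sum()
    auc = (rank_sum_pos - pos.size * (pos.size + 1) / 2.0) / (pos.size * neg.size)
    return float(auc)
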