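"""Synthetic validation study: cohort, repeated observers, both methods, stats.

Reproduces the design of an overlay-card validation on phantoms with known
truth: a cohort of glenoid phantoms is measured with the area-ratio
(best-fit-circle) method and with the comparison card by several simulated
observers on repeated occasions; the resulting tables feed ICC, one-way
ANOVA across the method/observer columns, and Bland–Altman agreement
between the two methods (observer-averaged values per phantom).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from .agreement import (
    BlandAltmanResult,
    GroupComparison,
    ICCResult,
    bland_altman,
    compare_groups,
    icc,
)
from .card_design import CardSpec, build_card
from .card_measure import measure_with_card
from .phantoms import DEFAULT_RADIUS_MM, GlenoidPhantom, ObserverModel, cohort, observe
from .sugaya import defect_fraction, fit_circle

__all__ = ["StudyConfig", "StudyReport", "run_study", "measure_scene"]

_SEED_MASK = 2**31 - 1


@dataclass(frozen=True)
class StudyConfig:
    """Parameters of one synthetic validation run (defaults = standard design)."""

    n_patients: int = 33
    n_observers: int = 3
    n_occasions: int = 2
    radius_mm: float = DEFAULT_RADIUS_MM
    noise_sd_mm: float = 0.2
    fraction_mean: float = 0.10
    fraction_sd: float = 0.08
    seed: int = 1
    card_diameter_mm: float = 50.0
    strips_per_quadrant: int = 5
    alpha_pct: float = 0.5
    defect_shape: str = "chord"


@dataclass
class StudyReport:
    """All measurements and statistics of one study run."""

    config: StudyConfig
    true_pct: np.ndarray  # (n_patients,)
    sugaya_pct: np.ndarray  # (n_occasions, n_observers, n_patients)
    card_pct: np.ndarray  # (n_occasions, n_observers, n_patients)
    inter_observer_icc: list[ICCResult] = field(default_factory=list)
    intra_observer_icc: list[ICCResult] = field(default_factory=list)
    anova: list[GroupComparison] = field(default_factory=list)
    bland_altman_results: list[BlandAltmanResult] = field(default_factory=list)

    @property
    def mean_inter_observer_icc(self) -> float:
        return float(np.mean([r.value for r in self.inter_observer_icc]))

    def to_dict(self) -> dict:
        return {
            "config": asdict(self.config),
            "true_pct": [round(v, 6) for v in self.true_pct.tolist()],
            "sugaya_pct": np.round(self.sugaya_pct, 6).tolist(),
            "card_pct": np.round(self.card_pct, 6).tolist(),
            "inter_observer_icc": [
                {"occasion": i, "value": r.value, "grade": r.grade}
                for i, r in enumerate(self.inter_observer_icc)
            ],
            "mean_inter_observer_icc": self.mean_inter_observer_icc,
            "intra_observer_icc": [
                {"observer": i, "value": r.value, "grade": r.grade}
                for i, r in enumerate(self.intra_observer_icc)
            ],
            "anova": [
                {"occasion": i, "F": r.statistic, "p": r.p_value}
                for i, r in enumerate(self.anova)
            ],
            "bland_altman": [
                {
                    "occasion": i,
                    "bias": r.bias,
                    "sd": r.sd_diff,
                    "loa_lower": r.loa_lower,
                    "loa_upper": r.loa_upper,
                    "ci_bias": list(r.ci_bias),
                    "n": r.n,
                }
                for i, r in enumerate(self.bland_altman_results)
            ],
        }


def measure_scene(card, rim, defect, alpha_pct: float = 0.5):
    """Both methods on one observed scene -> (sugaya_pct, card_pct, details)."""
    circle = fit_circle(rim)
    sres = defect_fraction(circle, defect)
    cres = measure_with_card(card, circle, defect, alpha_pct=alpha_pct)
    return sres.percent, cres.percent, (circle, sres, cres)


def _observer_models(cfg: StudyConfig) -> list[ObserverModel]:
    out = []
    for o in range(cfg.n_observers):
        obs_seed = int(
            np.random.SeedSequence([cfg.seed & _SEED_MASK, o]).generate_state(1)[0]
        ) & _SEED_MASK
        out.append(
            ObserverModel(
                rim_noise_sd=cfg.noise_sd_mm,
                defect_edge_noise_sd=cfg.noise_sd_mm,
                seed=obs_seed,
            )
        )
    return out


def run_study(cfg: StudyConfig = StudyConfig(), with_stats: bool = True) -> StudyReport:
    """Generate the cohort, simulate all measurements, compute the statistics."""
    card = build_card(
        CardSpec(cfg.card_diameter_mm / 2.0, cfg.strips_per_quadrant)
    )
    phantoms: list[GlenoidPhantom] = cohort(
        n_patients=cfg.n_patients,
        fraction_mean=cfg.fraction_mean,
        fraction_sd=cfg.fraction_sd,
        seed=cfg.seed,
        radius=cfg.radius_mm,
        shape=cfg.defect_shape,
    )
    models = _observer_models(cfg)
    shape = (cfg.n_occasions, cfg.n_observers, cfg.n_patients)
    sugaya_pct = np.zeros(shape)
    card_pct = np.zeros(shape)
    for t in range(cfg.n_occasions):
        for o, model in enumerate(models):
            for i, ph in enumerate(phantoms):
                rim, defect = observe(ph, model, occasion=t)
                s, c, _ = measure_scene(card, rim, defect, alpha_pct=cfg.alpha_pct)
                sugaya_pct[t, o, i] = s
                card_pct[t, o, i] = c
    report = StudyReport(
        config=cfg,
        true_pct=100.0 * np.array([ph.true_fraction for ph in phantoms]),
        sugaya_pct=sugaya_pct,
        card_pct=card_pct,
    )
    if not with_stats:
        return report
    for t in range(cfg.n_occasions):
        # inter-observer reliability of the card on this occasion
        report.inter_observer_icc.append(icc(card_pct[t].T))
        # method/observer mean comparison: area-ratio column + card observers
        columns = [sugaya_pct[t].mean(axis=0)] + [
            card_pct[t, o] for o in range(cfg.n_observers)
        ]
        report.anova.append(compare_groups(columns))
        # agreement between methods, observer-averaged per phantom
        report.bland_altman_results.append(
            bland_altman(card_pct[t].mean(axis=0), sugaya_pct[t].mean(axis=0))
        )
    if cfg.n_occasions >= 2:
        for o in range(cfg.n_observers):
            report.intra_observer_icc.append(
                icc(np.stack([card_pct[t, o] for t in range(cfg.n_occasions)], axis=1))
            )
    return report
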