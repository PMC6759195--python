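"""Engineered-strain simulation: enzyme fold-changes, product yields and
fit-quality summaries.

An x-fold change in gene expression is modeled as an x-fold change in the
corresponding enzyme's level (applied to all of its complexes); a fold of
0 is a knockout.  Product yield is the target reaction flux divided by
the glucose uptake flux in the *perturbed* steady state (mol per mol
glucose), with target reactions supplied explicitly — for products
outside the network a precursor drain serves as proxy, which is expected
to overpredict.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr

from kfitlab.core import ModelError
from kfitlab.elementary import SteadyState, steady_state
from kfitlab.kinetic import KineticResults, LocalFit, TrainingSet, compute_ssr

__all__ = ["PerturbationSpec", "YieldPrediction", "apply_perturbation",
           "predict_yield", "fit_summary"]


@dataclass
class PerturbationSpec:
    """Per-reaction enzyme fold-changes (0 = knockout)."""

    fold_changes: dict[str, float] = field(default_factory=dict)
    target_reaction: str | None = None
    experimental_yield: float | None = None

    def __post_init__(self):
        for rid, fold in self.fold_changes.items():
            if fold < 0:
                raise ModelError(f"negative fold change for {rid}")


@dataclass
class YieldPrediction:
    target_reaction: str
    target_flux: float
    uptake_flux: float
    predicted_yield: float
    stable: bool | None
    experimental_yield: float | None = None

    @property
    def percent_overprediction(self) -> float | None:
        if self.experimental_yield in (None, 0.0):
            return None
        return 100.0 * (self.predicted_yield - self.experimental_yield) \
            / self.experimental_yield


def _enzyme_levels_from_folds(model, fold_changes: dict[str, float]
                              ) -> dict[str, float]:
    levels: dict[str, float] = {}
    for rid, fold in fold_changes.items():
        rxn = model.reactions.get(rid)
        if rxn is None:
            raise ModelError(f"perturbation references unknown reaction {rid}")
        if rxn.enzyme_id is None:
            raise ModelError(f"reaction {rid} has no enzyme to perturb")
        levels[rxn.enzyme_id] = fold
    return levels


def apply_perturbation(
    fit: KineticResults | LocalFit, spec: PerturbationSpec
) -> SteadyState:
    """Steady state with each perturbed reaction's total enzyme scaled by
    its fold change (unperturbed enzymes stay at wild-type level)."""
    local = fit.best if isinstance(fit, KineticResults) else fit
    net = local.params.net
    levels = _enzyme_levels_from_folds(net.model, spec.fold_changes)
    return steady_state(net, local.params, levels, max_iter=400)


def predict_yield(
    state: SteadyState,
    target_reaction: str,
    uptake_reaction: str,
    experimental_yield: float | None = None,
) -> YieldPrediction:
    """Yield = target flux / glucose uptake flux (mol per mol glucose)."""
    v_target = state.flux(target_reaction)
    v_uptake = state.flux(uptake_reaction)
    if v_uptake <= 0:
        raise ModelError(
            "predicted no carbon uptake: uptake flux "
            f"{v_uptake:.3g} through {uptake_reaction}")
    return YieldPrediction(
        target_reaction=target_reaction,
        target_flux=v_target,
        uptake_flux=v_uptake,
        predicted_yield=v_target / v_uptake,
        stable=state.stable,
        experimental_yield=experimental_yield,
    )


def fit_summary(
    predictions: dict[str, SteadyState], train: TrainingSet
) -> dict:
    """Fractions of fitted fluxes within 1-4 SDs, Pearson correlation of
    predicted vs training fluxes, and per-strain SSR shares."""
    ssr, shares, _ = compute_ssr(predictions, train)
    devs, pred_all, obs_all = [], [], []
    for s in train.strains:
        st = predictions[s.strain_id]
        pred = st.as_flux_dict()
        for rid, (vobs, sd) in s.fluxes.items():
            vp = pred.get(rid, 0.0)
            devs.append(abs(vp - vobs) / sd)
            pred_all.append(vp)
            obs_all.append(vobs)
    devs = np.array(devs)
    n = max(len(devs), 1)
    within = {f"within_{k}_sd": float((devs <= k).sum() / n)
              for k in (1, 2, 3, 4)}
    if len(pred_all) >= 2 and np.std(obs_all) > 0 and np.std(pred_all) > 0:
        r, _ = pearsonr(pred_all, obs_all)
    else:
        r = np.nan
    return {
        "ssr": ssr,
        "n_fluxes": len(devs),
        **within,
        "pearson_r": float(r),
        "per_strain_ssr": shares,
    }
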