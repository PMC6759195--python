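"""Post-fit analyses: parameter covariance, regulation essentiality and
Michaelis-Menten parameter ranges.

Parameter uncertainty follows the Gauss-Newton approximation: with J the
Jacobian of the (unweighted) flux residuals with respect to the
elementary rate constants k and W the diagonal residual weights (1/SD^2),
H = J'WJ approximates the Hessian, the covariance is the pseudo-inverse
of H restricted to its identifiable subspace, SD is the square root of
the covariance diagonal, and CV(%) = 100 SD / |k|.  Rank deficiency is
expected — elementary constants arise as products of the two anchoring
variables — so null directions are reported as unidentifiable.

A substrate-level regulation is *nonessential* when the one-SD range of
its inhibitor binding constant has a lower bound of zero or below, i.e.
value - SD <= 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from kfitlab.core import ModelError
from kfitlab.elementary import machine_for
from kfitlab.kinetic import KineticResults, LocalFit, TrainingSet

__all__ = ["SensitivityReport", "RegulationEssentiality", "sensitivity",
           "essential_regulations", "mm_ranges"]

PINV_CUTOFF = 1e-10


@dataclass
class SensitivityReport:
    param_names: list[str]
    values: np.ndarray
    J: np.ndarray                # d residual / d k (unweighted residuals)
    W: np.ndarray                # diagonal weights (1/SD^2)
    H: np.ndarray
    covariance: np.ndarray
    sd: np.ndarray
    cv_percent: np.ndarray
    unidentifiable: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "param_names": self.param_names,
            "values": self.values.tolist(),
            "sd": self.sd.tolist(),
            "cv_percent": self.cv_percent.tolist(),
            "unidentifiable": self.unidentifiable,
        }


def sensitivity(fit: KineticResults | LocalFit, train: TrainingSet,
                ) -> SensitivityReport:
    """Covariance-based sensitivities of the elementary rate constants."""
    local = fit.best if isinstance(fit, KineticResults) else fit
    params = local.params
    net = params.net
    mach = machine_for(net)
    ns = net.n_steps
    nk = 2 * ns
    # identity parameterization: theta == [kf; kr]
    dkf = np.zeros((ns, nk))
    dkr = np.zeros((ns, nk))
    dkf[np.arange(ns), np.arange(ns)] = 1.0
    dkr[np.arange(ns), ns + np.arange(ns)] = 1.0

    rows_J, rows_w = [], []
    for s in train.strains:
        st = local.predictions.get(s.strain_id)
        if st is None:
            raise ModelError(f"fit has no prediction for strain {s.strain_id}")
        u = np.log(np.maximum(st.c, 1e-300))
        a, b = mach.rate_factors(u, params.k_fwd, params.k_rev)
        dv = mach.flux_sensitivities(u, st.x, a, b, params.k_fwd,
                                     params.k_rev, dkf, dkr)
        for rid, (_v_obs, sd) in s.fluxes.items():
            if rid in net.mechanisms:
                rows_J.append(dv[net.mechanisms.index(rid)])
            else:
                rows_J.append(np.zeros(nk))
            rows_w.append(1.0 / sd**2)
    J = np.vstack(rows_J)
    W = np.array(rows_w)
    H = J.T @ (W[:, None] * J)

    # pseudo-inverse on the identifiable subspace
    evals, evecs = np.linalg.eigh(H)
    cutoff = PINV_CUTOFF * max(evals.max(), 0.0)
    keep = evals > cutoff
    inv_evals = np.where(keep, 1.0 / np.where(keep, evals, 1.0), 0.0)
    cov = (evecs * inv_evals) @ evecs.T
    sd_vec = np.sqrt(np.maximum(np.diag(cov), 0.0))

    null_proj = ((evecs[:, ~keep] ** 2).sum(axis=1)
                 if np.any(~keep) else np.zeros(nk))
    names = [f"kf[{s.index}:{s.reaction_id}:{s.kind}]" for s in net.steps] + \
            [f"kr[{s.index}:{s.reaction_id}:{s.kind}]" for s in net.steps]
    values = np.concatenate([params.k_fwd, params.k_rev])
    unident = [names[i] for i in np.flatnonzero(null_proj > 1e-8)]
    cv = 100.0 * sd_vec / np.maximum(np.abs(values), 1e-300)
    return SensitivityReport(
        param_names=names, values=values, J=J, W=W, H=H, covariance=cov,
        sd=sd_vec, cv_percent=cv, unidentifiable=unident,
    )


@dataclass
class RegulationEssentiality:
    verdicts: list[dict]  # one entry per regulation
    n_essential: int
    n_total: int

    def to_json_dict(self) -> dict:
        return {"verdicts": self.verdicts, "n_essential": self.n_essential,
                "n_total": self.n_total}


def essential_regulations(
    fit: KineticResults | LocalFit, report: SensitivityReport
) -> RegulationEssentiality:
    """Classify each regulation by the value - SD <= 0 lower-bound rule.

    The inhibitor constant of a binding step is its association constant
    ``kf/kr``; its SD follows by the delta method from the covariance of
    the two elementary constants.  A regulation with several binding steps
    (noncompetitive) is essential when any of its constants is.
    """
    local = fit.best if isinstance(fit, KineticResults) else fit
    params = local.params
    net = params.net
    ns = net.n_steps
    by_reg: dict[tuple[str, str, str], list[int]] = {}
    for idx, key in net.inhibitor_steps.items():
        by_reg.setdefault(key, []).append(idx)

    verdicts = []
    n_ess = 0
    for (rxn, inh, mode), step_idxs in by_reg.items():
        entries = []
        essential = False
        for si in step_idxs:
            kf = params.k_fwd[si]
            kr = params.k_rev[si]
            ka = kf / kr
            var_f = report.covariance[si, si]
            var_r = report.covariance[ns + si, ns + si]
            cov_fr = report.covariance[si, ns + si]
            # delta method on ka = kf/kr
            g = np.array([1.0 / kr, -kf / kr**2])
            var = (g[0]**2 * var_f + g[1]**2 * var_r + 2 * g[0] * g[1] * cov_fr)
            sd = float(np.sqrt(max(var, 0.0)))
            ess = (ka - sd) > 0
            essential = essential or ess
            entries.append({"step": si, "value": float(ka), "sd": sd,
                            "essential": bool(ess)})
        n_ess += essential
        verdicts.append({
            "reaction": rxn, "inhibitor": inh, "mode": mode,
            "essential": bool(essential), "constants": entries,
        })
    return RegulationEssentiality(verdicts, n_ess, len(verdicts))


def mm_ranges(
    results: KineticResults,
    metabolomics: dict[str, tuple[float, float]],
    ssr_window: float = 0.10,
) -> tuple[list, dict]:
    """Km/Vmax ranges across near-optimal models and metabolomic spread.

    Internal concentrations are scaled to 1 at wild type, so a Km term
    acquires absolute units through the wild-type concentrations of the
    metabolites missing from its monomial.  For every model within
    ``ssr_window`` of the optimal SSR, each parameter is evaluated with
    every scaling concentration set one SD below and one SD above its
    mean; the reported range is the min/max over that model-by-extreme
    grid.  Parameters whose scaling metabolite lacks data are skipped
    (returned in the second element).  Elementary-constant ranges (mean
    +/- SD across the same models) are included under ``"elementary"``.
    """
    from kfitlab.kingaltman import king_altman

    best = results.best
    models = [f for f in results.fits
              if f.ssr <= (1.0 + ssr_window) * best.ssr]
    net = best.params.net

    out = []
    skipped: list[str] = []
    for rid in net.mechanisms:
        laws = [king_altman(net, rid, f.params.k_fwd, f.params.k_rev)
                for f in models]
        ref = laws[0]
        for term_i, term in enumerate(ref.km_terms):
            # metabolites missing from this term's monomial set its scale
            missing: dict[str, int] = {}
            target = {m: ref.substrates.count(m) for m in set(ref.substrates)}
            mono = term.monomial
            for met, cnt in target.items():
                present = 0
                symname = f"c_{met}"
                if symname in mono:
                    # crude monomial exponent parse via sympy
                    import sympy as sp

                    present = sp.sympify(mono).as_powers_dict().get(
                        ref.conc_symbols[met], 0)
                deficit = cnt - int(present)
                if deficit > 0:
                    missing[met] = deficit
            if any(m not in metabolomics for m in missing):
                skipped.append(f"{rid}:Km[{term.monomial}]")
                continue
            vals = []
            for law in laws:
                base = law.km_terms[term_i].value
                for sign in (-1.0, +1.0):
                    scale = 1.0
                    for met, d in missing.items():
                        mean, sd = metabolomics[met]
                        scale *= max(mean + sign * sd, 1e-300) ** d
                    vals.append(base * scale)
            scale_mean = 1.0
            for met, d in missing.items():
                scale_mean *= metabolomics[met][0] ** d
            term_out = type(term)(
                reaction_id=rid, kind="Km_term", monomial=term.monomial,
                expression=term.expression,
                value=ref.km_terms[term_i].value * scale_mean,
                range=(float(min(vals)), float(max(vals))),
                units=term.units)
            out.append(term_out)
        vvals = [law.vmax.value for law in laws]
        vmax = type(ref.vmax)(
            reaction_id=rid, kind="Vmax", monomial="1",
            expression=ref.vmax.expression, value=ref.vmax.value,
            range=(float(min(vvals)), float(max(vvals))), units="flux")
        out.append(vmax)

    kmat = np.array([np.concatenate([f.params.k_fwd, f.params.k_rev])
                     for f in models])
    elem = {
        "mean": kmat.mean(axis=0).tolist(),
        "sd": kmat.std(axis=0, ddof=0).tolist(),
        "lo": (kmat.mean(axis=0) - kmat.std(axis=0)).tolist(),
        "hi": (kmat.mean(axis=0) + kmat.std(axis=0)).tolist(),
        "n_models": len(models),
    }
    return out, {"elementary": elem, "skipped": skipped}
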