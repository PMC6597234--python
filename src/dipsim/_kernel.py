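"""Fused monthly update kernel for the agent arrays.

One pass over all agents per step runs the per-agent state machine:
postpartum recovery, the conception decision, BMI drift/noise, insulin
sensitivity (with the pregnancy resistance ramp and intervention
channels), glycemic index, treatment multiplier, the beta-cell/exposure
Euler update, the pregnancy clock, and due-detection for screening tests
and delivery. Event indices are returned compactly so the orchestrator
only touches the few agents with events each month.

Compiled with numba when available; a vectorised numpy twin provides the
fallback and a cross-check target. Both implementations must stay
numerically identical: a test compares them elementwise on random
inputs.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore[misc]
        if a and callable(a[0]):
            return a[0]

        def deco(f):
            return f
        return deco

GESTATION_WEEKS = 40.0


@njit(cache=False)
def _monthly_core_nb(n, alive, female, birth_t, t, dt, dt_weeks,
                     bmi, drift_mult, drift_ages, drift_rates, secular, noise,
                     bmi_off, s_mult, s_base, B, E, preg, gest_week, pp_end,
                     diag, diag_week, done_early, done_univ,
                     attend_early, attend_univ, sumG, sumT,
                     u_conc, fert_ages, fert_rates,
                     early_week, univ_week,
                     k_bmi, bmi_ref, s_min, rho_preg, g_max, g_thr,
                     k_decay, r_regen, e_rev, m_full, ramp_weeks,
                     mechanistic, G_np_out, G_eff_out,
                     idx_conc, idx_early, idx_univ, idx_del):  # pragma: no cover
    n_conc = 0
    n_early = 0
    n_univ = 0
    n_del = 0
    for i in range(n):
        if not alive[i]:
            G_np_out[i] = 1.0
            G_eff_out[i] = 1.0
            continue
        age = t - birth_t[i]
        if age < 0.0:
            age = 0.0
        # postpartum recovery
        if preg[i] == 2 and t >= pp_end[i]:
            preg[i] = 0
        # conception decision
        if female[i] and preg[i] == 0 and 15.0 <= age < 50.0:
            k = fert_ages.shape[0] - 1
            while k > 0 and fert_ages[k] > age:
                k -= 1
            if u_conc[i] < fert_rates[k] * dt:
                preg[i] = 1
                gest_week[i] = 0.0
                sumG[i] = 0.0
                sumT[i] = 0.0
                diag[i] = False
                done_early[i] = False
                done_univ[i] = False
                attend_early[i] = False
                attend_univ[i] = False
                idx_conc[n_conc] = i
                n_conc += 1
        # BMI drift spline (linear interpolation, clamped ends)
        if age <= drift_ages[0]:
            dr = drift_rates[0]
        elif age >= drift_ages[-1]:
            dr = drift_rates[-1]
        else:
            k = 1
            while drift_ages[k] < age:
                k += 1
            f = (age - drift_ages[k - 1]) / (drift_ages[k] - drift_ages[k - 1])
            dr = drift_rates[k - 1] + f * (drift_rates[k] - drift_rates[k - 1])
        b = bmi[i] + (dr * drift_mult[i] + secular) * dt + noise[i]
        if b < 10.0:
            b = 10.0
        bmi[i] = b
        be = b + bmi_off[i]
        if be < 10.0:
            be = 10.0
        pregnant = preg[i] == 1
        if mechanistic:
            pen = np.exp(-k_bmi * max(0.0, be - bmi_ref))
            Bv = B[i] if B[i] > 0.0 else 0.0
            s_np = s_base[i] * s_mult[i] * pen
            if s_np < s_min:
                s_np = s_min
            elif s_np > 1.0:
                s_np = 1.0
            if Bv > 0.0:
                g_np = 1.0 / max(s_np * Bv, 1.0 / g_max)
            else:
                g_np = g_max
            if g_np > g_max:
                g_np = g_max
            G_np_out[i] = g_np
            if pregnant:
                gw = gest_week[i]
                if gw > GESTATION_WEEKS:
                    gw = GESTATION_WEEKS
                pm = 1.0 - rho_preg * gw / GESTATION_WEEKS
            else:
                pm = 1.0
            s = s_base[i] * s_mult[i] * pen * pm
            if s < s_min:
                s = s_min
            elif s > 1.0:
                s = 1.0
            if Bv > 0.0:
                g_raw = 1.0 / max(s * Bv, 1.0 / g_max)
            else:
                g_raw = g_max
            if g_raw > g_max:
                g_raw = g_max
            tm = 1.0
            if pregnant and diag[i]:
                w = gest_week[i] - diag_week[i]
                if w < 0.0:
                    w = 0.0
                r = w / ramp_weeks
                if r > 1.0:
                    r = 1.0
                tm = 1.0 - (1.0 - m_full) * r
            g_eff = g_raw * tm
            G_eff_out[i] = g_eff
            # beta-cell / exposure Euler update on the chronic index
            y = g_np - g_thr
            if y < 0.0:
                y = 0.0
            regen = r_regen * (1.0 - Bv) if E[i] < e_rev else 0.0
            Bn = Bv + (regen - k_decay * y * Bv) * dt
            if Bn < 0.0:
                Bn = 0.0
            elif Bn > 1.0:
                Bn = 1.0
            B[i] = Bn
            E[i] = E[i] + y * dt
        else:
            g_eff = 1.0
            G_np_out[i] = 1.0
            G_eff_out[i] = 1.0
        if pregnant:
            sumG[i] += g_eff * dt
            sumT[i] += dt
            gest_week[i] += dt_weeks
            gw = gest_week[i]
            if attend_early[i] and not done_early[i] and gw >= early_week:
                done_early[i] = True
                idx_early[n_early] = i
                n_early += 1
            if attend_univ[i] and not done_univ[i] and gw >= univ_week:
                done_univ[i] = True
                idx_univ[n_univ] = i
                n_univ += 1
            if gw >= GESTATION_WEEKS:
                idx_del[n_del] = i
                n_del += 1
    return n_conc, n_early, n_univ, n_del


def _monthly_core_np(n, alive, female, birth_t, t, dt, dt_weeks,
                     bmi, drift_mult, drift_ages, drift_rates, secular, noise,
                     bmi_off, s_mult, s_base, B, E, preg, gest_week, pp_end,
                     diag, diag_week, done_early, done_univ,
                     attend_early, attend_univ, sumG, sumT,
                     u_conc, fert_ages, fert_rates,
                     early_week, univ_week,
                     k_bmi, bmi_ref, s_min, rho_preg, g_max, g_thr,
                     k_decay, r_regen, e_rev, m_full, ramp_weeks,
                     mechanistic, G_np_out, G_eff_out,
                     idx_conc, idx_early, idx_univ, idx_del):
    """Vectorised twin of the numba kernel (identical results)."""
    s = slice(0, n)
    a = alive[s]
    age = np.maximum(t - birth_t[s], 0.0)
    # postpartum recovery
    rec = a & (preg[s] == 2) & (t >= pp_end[s])
    preg[s][rec] = 0
    # conception
    fk = np.clip(np.searchsorted(fert_ages, age, side="right") - 1, 0,
                 len(fert_ages) - 1)
    conc = (a & female[s] & (preg[s] == 0) & (age >= 15.0) & (age < 50.0)
            & (u_conc[s] < fert_rates[fk] * dt))
    wc = np.flatnonzero(conc)
    preg[s][conc] = 1
    for arr in (gest_week, sumG, sumT):
        arr[s][conc] = 0.0
    for arr in (diag, done_early, done_univ, attend_early, attend_univ):
        arr[s][conc] = False
    idx_conc[:wc.size] = wc
    # BMI
    dr = np.interp(age, drift_ages, drift_rates)
    b = np.maximum(bmi[s] + (dr * drift_mult[s] + secular) * dt + noise[s], 10.0)
    bmi[s] = np.where(a, b, bmi[s])
    be = np.maximum(bmi[s] + bmi_off[s], 10.0)
    pregnant = preg[s] == 1
    if mechanistic:
        pen = np.exp(-k_bmi * np.maximum(0.0, be - bmi_ref))
        Bv = np.maximum(B[s], 0.0)
        s_np = np.clip(s_base[s] * s_mult[s] * pen, s_min, 1.0)
        g_np = np.where(Bv > 0, 1.0 / np.maximum(s_np * Bv, 1.0 / g_max), g_max)
        np.minimum(g_np, g_max, out=g_np)
        pm = np.where(pregnant,
                      1.0 - rho_preg * np.minimum(gest_week[s], GESTATION_WEEKS)
                      / GESTATION_WEEKS, 1.0)
        sv = np.clip(s_base[s] * s_mult[s] * pen * pm, s_min, 1.0)
        g_raw = np.where(Bv > 0, 1.0 / np.maximum(sv * Bv, 1.0 / g_max), g_max)
        np.minimum(g_raw, g_max, out=g_raw)
        w = np.maximum(gest_week[s] - diag_week[s], 0.0)
        tm = np.where(pregnant & diag[s],
                      1.0 - (1.0 - m_full) * np.minimum(w / ramp_weeks, 1.0), 1.0)
        g_eff = g_raw * tm
        y = np.maximum(0.0, g_np - g_thr)
        regen = r_regen * (1.0 - Bv) * (E[s] < e_rev)
        Bn = np.clip(Bv + (regen - k_decay * y * Bv) * dt, 0.0, 1.0)
        B[s] = np.where(a, Bn, B[s])
        E[s] = np.where(a, E[s] + y * dt, E[s])
        G_np_out[s] = np.where(a, g_np, 1.0)
        G_eff_out[s] = np.where(a, g_eff, 1.0)
    else:
        g_eff = np.ones(n)
        G_np_out[s] = 1.0
        G_eff_out[s] = 1.0
    upd = a & pregnant
    sumG[s] += np.where(upd, g_eff * dt, 0.0)
    sumT[s] += np.where(upd, dt, 0.0)
    gest_week[s] += np.where(upd, dt_weeks, 0.0)
    gw = gest_week[s]
    due_e = upd & attend_early[s] & ~done_early[s] & (gw >= early_week)
    done_early[s][due_e] = True
    we = np.flatnonzero(due_e)
    idx_early[:we.size] = we
    due_u = upd & attend_univ[s] & ~done_univ[s] & (gw >= univ_week)
    done_univ[s][due_u] = True
    wu = np.flatnonzero(due_u)
    idx_univ[:wu.size] = wu
    due_d = upd & (gw >= GESTATION_WEEKS)
    wd = np.flatnonzero(due_d)
    idx_del[:wd.size] = wd
    return wc.size, we.size, wu.size, wd.size


monthly_core = _monthly_core_nb if HAVE_NUMBA else _monthly_core_np
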