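"""Independent brute-force re-derivations of the pipeline's decisions.

Written as naive per-item scans over raw fields, deliberately sharing no code
with the package: every branch, criterion and eligibility decision is
recomputed from first principles so the pipeline can be checked against it.
"""

import datetime as dt
import math


def _fam(claim):
    if claim.route.value in ("oral", "rectal"):
        return "oral"
    if claim.formulation.value == "long_acting":
        return "la"
    return "sa"


def oracle_clean_patient(patient_claims, intervals, config):
    """Expected (cleaned_quantity, cleaned_days_supply, branch-per-field) per claim.

    Operates on the raw fields of one patient's claims only.
    """
    out = {}
    claims = sorted(patient_claims, key=lambda c: (c.dispense_date, c.claim_id))
    for c in claims:
        fam = _fam(c)
        q = c.quantity
        q_branch = None
        if fam == "sa":
            q_branch = "sa_keep"
            if c.unit_cost and c.total_cost:
                if abs(c.quantity * c.unit_cost - c.total_cost) / c.total_cost > config.cost_mismatch_tolerance:
                    q = round(c.total_cost / c.unit_cost, 2)
                    q_branch = "sa_quantity_repair"
        if fam in ("oral", "sa"):
            nxt_dates = [
                d.dispense_date
                for d in claims
                if _fam(d) == fam
                and d.drug == c.drug
                and d.formulation == c.formulation
                and d.dispense_date > c.dispense_date
            ]
            if nxt_dates and (min(nxt_dates) - c.dispense_date).days <= config.next_fill_window_days:
                ds, ds_branch = c.days_supply, "oral_keep"
            else:
                ds = max(1, int(math.floor(q / config.oral_fallback_divisor + 0.5)))
                ds_branch = "oral_fallback"
        else:
            m = dict(intervals.items())[c.drug]
            later = [
                d.dispense_date
                for d in claims
                if _fam(d) == "la" and d.dispense_date > c.dispense_date
            ]
            if c.days_supply > m:
                ds, ds_branch = c.days_supply, "la_keep"
            elif not later:
                ds, ds_branch = m, "la_set_min_interval"
            else:
                gap = (min(later) - c.dispense_date).days
                if gap < m:
                    ds, ds_branch = gap, "la_set_gap"
                else:
                    ds, ds_branch = m, "la_set_min_interval"
        out[c.claim_id] = (q, ds, q_branch, ds_branch)
    return out


def oracle_cohort(patients, claims, config):
    """Expected disposition per candidate: reason string or 'retained'."""
    by_pat = {}
    for c in claims:
        by_pat.setdefault(c.patient_id, []).append(c.dispense_date)
    pat = {p.patient_id: p for p in patients}
    out = {}
    for pid, dates in by_pat.items():
        dates = sorted(dates)
        in_window = [d for d in dates if config.accrual_start <= d <= config.accrual_end]
        if not in_window:
            continue
        p = pat[pid]
        first_ever = dates[0]
        index = first_ever if config.accrual_start <= first_ever <= config.accrual_end else None
        ref = index if index is not None else in_window[0]
        age = ref.year - p.birth_date.year - (
            (ref.month, ref.day) < (p.birth_date.month, p.birth_date.day)
        )
        if not p.dementia:
            out[pid] = "no_dementia"
        elif age < config.min_age_years:
            out[pid] = "under_age"
        elif index is None or any(
            0 < (index - d).days <= config.washout_days for d in dates
        ):
            out[pid] = "prior_use"
        elif not any(
            0 < (d - index).days <= config.followup_days for d in dates
        ):
            out[pid] = "no_subsequent_rx"
        else:
            out[pid] = "retained"
    return out


def oracle_eligible_ids(patient_claims, index_date, timepoint_days, config, use_cleaned):
    """Expected contributing claim ids at one timepoint, by naive scan."""
    ids = set()
    for c in patient_claims:
        if timepoint_days == 0:
            if c.dispense_date == index_date:
                ids.add(c.claim_id)
            continue
        target = index_date + dt.timedelta(days=timepoint_days)
        ds = c.cleaned_days_supply if use_cleaned else c.days_supply
        dispensed_in_window = 0 < (target - c.dispense_date).days < config.lookback_days or (
            c.dispense_date == target
        )
        covers = c.dispense_date <= target and (target - c.dispense_date).days < ds
        if dispensed_in_window and covers:
            ids.add(c.claim_id)
    return ids
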