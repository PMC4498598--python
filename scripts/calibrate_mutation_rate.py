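"""Calibrate the per-scenario mutation rate of the study grid.

For each scenario (prevalence window x penetrance model x loci count) this
script finds the mutation rate rho at which the median number of segregating
causative mutations per *accepted* population equals the scenario's
reference median (coalor.study.REFERENCE_PER_POPULATION_MEDIANS).

The accepted-population median is a non-decreasing step function of rho, so
the set of rates attaining the target median is an interval.  The script
locates both edges of that interval by bisection on the predicates
``median >= target`` and ``median > target`` and reports the geometric
midpoint, which centres the calibrated rate on the plateau instead of on an
edge.  Each evaluation rejection-samples populations of N = 10,000 until
``--accepted`` datasets are in the window (default 250, capped at
``--max-attempts-per-eval`` candidate simulations).

Usage:
    python scripts/calibrate_mutation_rate.py [--loci 1 2] [--accepted 250]
        [--seed 20150710] [--out rates.json]

Writes a JSON map {"window,model,loci": rate} and prints a ready-to-paste
CALIBRATED_RATES literal.  Expect a runtime of tens of minutes for the full
grid; pass e.g. ``--only rare,mult_0.3,1`` to calibrate a single scenario.
"""

from __future__ import annotations

import argparse
import json
import sys
import time

import numpy as np

from coalor.penetrance import PenetranceModel
from coalor.scenario import PREVALENCE_WINDOWS, ScenarioConfig, simulate_candidate, _attempt_rng
from coalor.study import MODELS, REFERENCE_PER_POPULATION_MEDIANS

#: Mean total branch length of a Kingman tree with n=10,000 leaves,
#: 2 * sum_{i<n} 1/i; used only to seed the search.
_MEAN_TOTAL_LENGTH = 19.574


def accepted_median(window, model, loci, rho, accepted_target, cap, seed):
    """Median segregating count over accepted datasets at rate ``rho``.

    Returns (median, acceptance_rate); median is NaN if fewer than 30
    datasets were accepted within the attempt cap.
    """
    lo, hi = PREVALENCE_WINDOWS[window]
    cfg = ScenarioConfig(
        penetrance=MODELS[model],
        loci=loci,
        mutation_rate=rho,
        prevalence_window=(lo, hi),
        target_accepted=accepted_target,
        max_attempts=cap,
        seed=seed,
    )
    seg = []
    attempts = 0
    while len(seg) < accepted_target and attempts < cap:
        ds = simulate_candidate(cfg, _attempt_rng(seed, attempts), attempts)
        attempts += 1
        if lo <= ds.prevalence < hi:
            seg.append(ds.n_segregating)
    rate = len(seg) / attempts if attempts else 0.0
    if len(seg) < 30:
        return float("nan"), rate
    return float(np.median(seg)), rate


def find_edge(predicate, rho_lo, rho_hi, tol=1.04):
    """Bisect (in log space) the boundary of a monotone predicate on rho."""
    while rho_hi / rho_lo > tol:
        mid = (rho_lo * rho_hi) ** 0.5
        if predicate(mid):
            rho_hi = mid
        else:
            rho_lo = mid
    return (rho_lo * rho_hi) ** 0.5


def calibrate_scenario(window, model, loci, target, accepted, cap, seed, log=print):
    evals = {}

    def median_at(rho):
        rho = round(rho, 6)
        if rho not in evals:
            med, acc = accepted_median(window, model, loci, rho, accepted, cap, seed)
            evals[rho] = med
            log("  rho=%-8.4f median=%-6s acceptance=%.3g" % (rho, med, acc))
        return evals[rho]

    # bracket the target median; per-locus rate scales ~1/loci for a fixed
    # joint mutation supply
    rho = max(target / _MEAN_TOTAL_LENGTH / loci, 1e-3)
    while not median_at(rho) >= target:  # NaN-safe: NaN => infeasible, go up
        if np.isnan(median_at(rho)):
            rho *= 1.6
            continue
        rho *= 1.6
    hi = rho
    lo = rho / 1.6
    while np.isnan(median_at(lo)) or median_at(lo) >= target:
        lo /= 1.6
        if lo < 1e-5:
            break

    left = find_edge(lambda r: median_at(r) >= target, lo, hi)
    # right edge: smallest rho with median > target
    hi2 = left
    while not median_at(hi2) > target:
        hi2 *= 1.3
    right = find_edge(lambda r: median_at(r) > target, left / 1.3, hi2)
    return float((left * right) ** 0.5)


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__.splitlines()[0])
    ap.add_argument("--loci", type=int, nargs="+", default=[1, 2])
    ap.add_argument("--accepted", type=int, default=250,
                    help="accepted datasets per evaluation")
    ap.add_argument("--max-attempts-per-eval", type=int, default=80_000)
    ap.add_argument("--seed", type=int, default=20150710)
    ap.add_argument("--out", default=None, help="write JSON rate map here")
    ap.add_argument("--only", default=None,
                    help="comma-separated window,model,loci to calibrate one cell")
    args = ap.parse_args(argv)

    cells = [k for k in sorted(REFERENCE_PER_POPULATION_MEDIANS) if k[2] in args.loci]
    if args.only:
        w, m, l = args.only.split(",")
        cells = [(w, m, int(l))]

    rates = {}
    for window, model, loci in cells:
        target = REFERENCE_PER_POPULATION_MEDIANS[(window, model, loci)]
        t0 = time.time()
        print("calibrating %s / %s / %d loci (target median %d)"
              % (window, model, loci, target))
        rho = calibrate_scenario(
            window, model, loci, target, args.accepted,
            args.max_attempts_per_eval, args.seed,
        )
        rates["%s,%s,%d" % (window, model, loci)] = rho
        print("-> rho = %.4f   (%.0f s)" % (rho, time.time() - t0))
        sys.stdout.flush()

    print("\nCALIBRATED_RATES = {")
    for key, rho in rates.items():
        w, m, l = key.split(",")
        print('    (%r, %r, %s): %.4f,' % (w, m, l, rho))
    print("}")
    if args.out:
        with open(args.out, "w") as fh:
            json.dump(rates, fh, indent=1)


if __name__ == "__main__":
    main()
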