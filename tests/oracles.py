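"""Independent reference implementations used only as test oracles.

These are deliberately written in a different style from the package
(scalar loops, explicit step-by-step bookkeeping) so agreement is evidence
of correctness rather than shared code.
"""

import math

import numpy as np

MID_DOY = [15, 46, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349]
DAYS = [31, 28.25, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]


def thornthwaite_pet_scalar(tmean_12, latitude):
    """Hand-style Thornthwaite PET for one calendar year (12 values)."""
    heat = 0.0
    for t in tmean_12:
        if t > 0:
            heat += (t / 5.0) ** 1.514
    heat = max(heat, 1e-9)
    a = (6.75e-7 * heat**3 - 7.71e-5 * heat**2 + 1.792e-2 * heat + 0.49239)
    out = []
    for m, t in enumerate(tmean_12):
        if t <= 0:
            out.append(0.0)
            continue
        pet = 16.0 * (10.0 * t / heat) ** a
        decl = 0.409 * math.sin(2 * math.pi * MID_DOY[m] / 365.0 - 1.39)
        x = -math.tan(math.radians(latitude)) * math.tan(decl)
        x = min(1.0, max(-1.0, x))
        daylen = 24.0 / math.pi * math.acos(x)
        out.append(pet * (daylen / 12.0) * (DAYS[m] / 30.0))
    return out


def tm_ledger(tmean, precip, pet, whc=150.0, snow_all=0.0, rain_all=6.0,
              melt_coef=2.0, spinup=True):
    """Step-by-step Thornthwaite-Mather ledger, one month at a time.

    Returns dict of lists: aet, deficit, soil, snow, runoff, plus the store
    levels after spin-up (soil0, snow0).
    """
    n = len(tmean)

    def one_step(t, p, e, days, soil, snow):
        if t <= snow_all:
            fs = 1.0
        elif t >= rain_all:
            fs = 0.0
        else:
            fs = (rain_all - t) / (rain_all - snow_all)
        snowfall = p * fs
        rain = p - snowfall
        snow = snow + snowfall
        melt = min(snow, melt_coef * max(t, 0.0) * days)
        snow = snow - melt
        w = rain + melt
        if w >= e:
            aet = e
            extra = w - e
            rech = min(extra, whc - soil)
            soil = soil + rech
            runoff = extra - rech
        else:
            withdrawal = soil * (1.0 - math.exp(-(e - w) / whc))
            aet = w + withdrawal
            soil = soil - withdrawal
            runoff = 0.0
        return aet, runoff, soil, snow

    soil, snow = 0.0, 0.0
    if spinup:
        for m in range(min(12, n)):
            _, _, soil, snow = one_step(tmean[m], precip[m], pet[m],
                                        DAYS[m % 12], soil, snow)
    res = {"aet": [], "deficit": [], "soil": [], "snow": [], "runoff": [],
           "soil0": soil, "snow0": snow}
    for m in range(n):
        aet, runoff, soil, snow = one_step(tmean[m], precip[m], pet[m],
                                           DAYS[m % 12], soil, snow)
        res["aet"].append(aet)
        res["deficit"].append(pet[m] - aet)
        res["soil"].append(soil)
        res["snow"].append(snow)
        res["runoff"].append(runoff)
    return res


def auc_bruteforce(scores, labels):
    """Pairwise concordance probability, ties counted one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))


def threshold_bruteforce(probs, labels, method, grid=None):
    """Best objective over a dense cutoff grid plus all observed values."""
    probs = np.asarray(probs, float)
    labels = np.asarray(labels, int)
    if grid is None:
        grid = np.arange(0.0, 1.0005, 0.001)
    cands = np.unique(np.concatenate([grid, probs, [0.0, 1.0]]))
    best = -np.inf
    for t in cands:
        pred = probs > t
        tp = int(np.sum(pred & (labels == 1)))
        fn = int(np.sum(~pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        tn = int(np.sum(~pred & (labels == 0)))
        n = tp + fn + fp + tn
        sens = tp / (tp + fn)
        spec = tn / (fp + tn)
        if method == "max_sens_spec":
            obj = sens + spec
        else:
            po = (tp + tn) / n
            pe = ((tp + fn) * (tp + fp) + (fp + tn) * (fn + tn)) / n**2
            obj = 0.0 if pe >= 1.0 else (po - pe) / (1.0 - pe)
        best = max(best, obj)
    return best
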