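"""Brute-force recount oracles, written directly from the session records.

These deliberately re-derive every metric with plain loops and no shared
code with :mod:`cogbattery.scoring`, so they can serve as independent
checks of the scoring module.
"""

from __future__ import annotations


def recount_conditions(session) -> dict:
    """condition -> (k, n) recomputed trial by trial."""
    out: dict[str, list[int]] = {}
    for t in session.trials:
        if t.get("is_practice"):
            continue
        cond = t["condition"]
        k, n = out.setdefault(cond, [0, 0])
        if session.task == "mot":
            out[cond][0] += t["n_correct"]
            out[cond][1] += t["n_targets"]
        elif session.task == "lib":
            if t["peripheral_correct"] is None:
                continue
            out[cond][1] += 1
            if t["peripheral_correct"]:
                out[cond][0] += 1
        else:
            out[cond][1] += 1
            if t["correct"]:
                out[cond][0] += 1
    return {c: (k, n) for c, (k, n) in out.items()}


def recount_signal(session) -> tuple[float, float]:
    """(hit rate, false-alarm rate) recomputed trial by trial."""
    sig_key = "is_go" if session.task == "gonogo" else "is_repeat"
    hits = n_sig = fas = n_noise = 0
    for t in session.trials:
        if t.get("is_practice"):
            continue
        if t[sig_key]:
            n_sig += 1
            if t["responded"]:
                hits += 1
        else:
            n_noise += 1
            if t["responded"]:
                fas += 1
    return hits / n_sig, fas / n_noise


def recount_hr_by_distance(session, distance_class: str) -> tuple[int, int]:
    """(hits, repeats) over second presentations of one distance class."""
    hits = n = 0
    for t in session.trials:
        if t["is_repeat"] and t["distance_class"] == distance_class:
            n += 1
            if t["responded"]:
                hits += 1
    return hits, n


def recount_mean_rt(session) -> dict:
    out: dict[str, list[float]] = {}
    for t in session.trials:
        if t.get("is_practice"):
            continue
        if t["correct"] and t.get("rt_ms") is not None:
            out.setdefault(t["condition"], []).append(t["rt_ms"])
    return {c: sum(v) / len(v) for c, v in out.items()}


def recount_switch_cost(session) -> dict:
    """task_type -> cost, recomputed from raw trials."""
    rts: dict[tuple, list[float]] = {}
    for t in session.trials:
        if t["is_practice"] or t["is_switch"] is None or not t["correct"]:
            continue
        rts.setdefault((t["task_type"], t["is_switch"]), []).append(t["rt_ms"])
    out = {}
    for task_type in ("odd_even", "high_low"):
        sw = rts.get((task_type, True))
        ns = rts.get((task_type, False))
        if sw and ns:
            out[task_type] = sum(sw) / len(sw) - sum(ns) / len(ns)
    return out
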