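"""Desk-scale reproductions of the six study designs on synthetic cohorts.

Each experiment generates its cohort with the simulator, runs the matching
analysis chain and writes CSV tables, optional figures, and a
machine-readable JSON summary of group means, SEMs and test results.

  exp1  SJL behaviour, normal diet: no-wheel (n=5) vs wheel (n=9) onset
        delays across the jet-lag week.
  exp2  SJL peripheral clocks, normal diet: control / SJL / SJL+wheel
        bioluminescence acrophases measured the Thursday after the shift.
  exp3  exp1 under high-fat diet (n=10 vs n=8).
  exp4  exp2 under high-fat diet (n=6 per group).
  exp5  6-h advance: no-wheel vs wheel peripheral acrophases after the shift.
  exp6  free-running period in DD: no-wheel (n=9, tau 24.00) vs wheel
        (n=7, tau 23.50) chi-squared periodograms.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import _circular as circ
from .cosinor import cosinor_fit, group_acrophase, normalize_to_daily_mean
from .errors import InvalidArgumentError
from .onset import detect_onsets, double_plot, onset_delays
from .periodogram import chi_squared_periodogram
from .schedules import clock_to_zt, make_advance, make_dd, make_ld, make_sjl
from .simulate import (
    ORGANS,
    preset,
    organ_profile,
    simulate_activity,
    simulate_bioluminescence,
    write_activity_csv,
)
from .stats import compare_groups

EXPERIMENTS = ("exp1", "exp2", "exp3", "exp4", "exp5", "exp6")

BASELINE_DAYS = range(1, 8)
THURSDAY = 13          # 4th weekday after the weekend shift (days 8-9)
ADVANCE_MEASURE_DAY = 11


def _rng(seed: int, *stream) -> np.random.Generator:
    return np.random.default_rng([int(seed)] + [int(s) for s in stream])


def _round(x, nd=4):
    if isinstance(x, dict):
        return {k: _round(v, nd) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round(v, nd) for v in x]
    if isinstance(x, (float, np.floating)):
        return round(float(x), nd)
    if isinstance(x, (int, np.integer)):
        return int(x)
    return x


def _write_summary(summary: dict, out_dir: Path) -> Path:
    path = out_dir / "summary.json"
    path.write_text(json.dumps(_round(summary), sort_keys=True, indent=2) + "\n")
    return path


def _comparison_rows(name: str, res) -> list:
    rows = [
        {
            "comparison": name,
            "pair": " vs ".join(res.groups),
            "test": res.test_name,
            "statistic": res.statistic,
            "p_value": res.p_value,
        }
    ]
    for (a, b), p in res.posthoc or []:
        rows.append(
            {
                "comparison": name,
                "pair": f"{a} vs {b}",
                "test": res.test_name + " (post-hoc)",
                "statistic": float("nan"),
                "p_value": p,
            }
        )
    return rows


def _comparison_summary(res) -> dict:
    out = {
        "test": res.test_name,
        "statistic": res.statistic,
        "p_value": res.p_value,
        "parametric": bool(res.parametric),
    }
    if res.posthoc:
        out["posthoc"] = {f"{a} vs {b}": p for (a, b), p in res.posthoc}
    return out


def _save_actogram(rec, out_dir: Path, label: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = double_plot(rec)
    fig, ax = plt.subplots(figsize=(6, 0.35 * mat.n_days + 1))
    ax.imshow(mat.values, aspect="auto", cmap="Greys", interpolation="nearest")
    ax.set_xlabel("double-plotted time (bins, 48 h)")
    ax.set_ylabel("day")
    ax.set_title(f"actogram {label}")
    fig.tight_layout()
    fig.savefig(out_dir / f"actogram_{label}.png", dpi=110)
    plt.close(fig)


def _save_periodogram_fig(result, out_dir: Path, label: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(result.periods, result.q_stat, label="$Q_P$")
    ax.plot(result.periods, result.significance_line, "--", label="p=0.05 line")
    ax.axvline(result.best_period, color="r", lw=0.8)
    ax.set_xlabel("period (h)")
    ax.set_ylabel("Q")
    ax.legend()
    ax.set_title(f"chi-squared periodogram {label} (best {result.best_period:.2f} h)")
    fig.tight_layout()
    fig.savefig(out_dir / f"periodogram_{label}.png", dpi=110)
    plt.close(fig)


def _activity_cohort(sched, cfg, n, seed, group_idx, group, out_dir, save_csv=True):
    """Simulate n animals, detect onsets, fill delays vs the baseline week."""
    series = []
    for a in range(n):
        rng = _rng(seed, group_idx, a)
        rec = simulate_activity(sched, cfg, rng=rng, animal_id=f"{group}_{a + 1:02d}")
        if save_csv and a == 0:
            write_activity_csv(rec, out_dir / f"activity_{rec.animal_id}.csv")
        s = onset_delays(detect_onsets(rec, sched), BASELINE_DAYS)
        series.append((rec, s))
    return series


def _onset_table(groups: Dict[str, list]) -> pd.DataFrame:
    rows = []
    for group, series in groups.items():
        for _, s in series:
            for d, (onset, delay) in enumerate(zip(s.onsets, s.delays), start=1):
                rows.append(
                    {
                        "group": group,
                        "animal_id": s.animal_id,
                        "day": d,
                        "onset_zt": onset,
                        "delay_h": delay,
                    }
                )
    return pd.DataFrame(rows)


def _sjl_behavior_experiment(presets: Dict[str, tuple], seed: int, out_dir: Path,
                             make_plots: bool) -> dict:
    """Shared engine for exp1/exp3: SJL week, two groups, per-day delays."""
    sched = make_sjl(7, 6.0, 5)
    groups = {}
    for gi, (group, (preset_name, n)) in enumerate(presets.items()):
        groups[group] = _activity_cohort(
            sched, preset(preset_name), n, seed, gi, group, out_dir
        )
    table = _onset_table(groups)
    table.to_csv(out_dir / "onsets.csv", index=False)

    summary = {"schedule": "SJL 7+2+5 days, 6-h weekend delay", "groups": {}}
    for group, series in groups.items():
        delays = np.vstack([s.delays for _, s in series])
        summary["groups"][group] = {
            "n": len(series),
            "day_mean_delay_h": delays.mean(axis=0).tolist(),
            "day_sem_delay_h": (delays.std(axis=0, ddof=1) / np.sqrt(len(series))).tolist(),
        }

    comp_rows, tests = [], {}
    gnames = list(groups)
    for day in range(8, sched.n_days + 1):
        data = {
            g: [s.delays[day - 1] for _, s in groups[g] if not np.isnan(s.delays[day - 1])]
            for g in gnames
        }
        res = compare_groups(data)
        tests[f"day{day}_delay"] = _comparison_summary(res)
        comp_rows += _comparison_rows(f"day{day}_delay", res)
    summary["tests"] = tests
    pd.DataFrame(comp_rows).to_csv(out_dir / "comparisons.csv", index=False)

    if make_plots:
        for group, series in groups.items():
            _save_actogram(series[0][0], out_dir, group)
    return summary


def _biolum_experiment(designs, seed: int, out_dir: Path, make_plots: bool,
                       measure_day: int) -> dict:
    """Shared engine for exp2/exp4/exp5: behaviour sim -> phase shift ->
    six-point bioluminescence -> cosinor -> group comparison per organ.

    ``designs`` maps group label to (schedule, SimConfig, wheel_access, n).
    """
    fits = {organ: {} for organ in ORGANS}
    rows = []
    for gi, (group, (sched, cfg, wheel, n)) in enumerate(designs.items()):
        for a in range(n):
            rng = _rng(seed, gi, a)
            animal = f"{group}_{a + 1:02d}"
            rec = simulate_activity(sched, cfg, rng=rng, animal_id=animal)
            s = onset_delays(detect_onsets(rec, sched), BASELINE_DAYS)
            shift = float(s.delays[measure_day - 1])
            for organ in ORGANS:
                prof = organ_profile(organ, wheel=wheel)
                series = simulate_bioluminescence(
                    shift, prof, cfg, sched, rng=rng, animal_id=animal
                )
                series = normalize_to_daily_mean(series)
                zts = [clock_to_zt(c, sched) for c in series.sample_clock_times]
                fit = cosinor_fit(zts, series.normalized_pct)
                fits[organ].setdefault(group, []).append(fit)
                rows.append(
                    {
                        "group": group,
                        "animal_id": animal,
                        "organ": organ,
                        "behavior_shift_h": shift,
                        "mesor": fit.mesor,
                        "amplitude_pct": fit.amplitude,
                        "acrophase_zt": fit.acrophase_zt,
                        "p_rhythm": fit.p_zero_amplitude,
                    }
                )
    df = pd.DataFrame(rows)
    df.to_csv(out_dir / "cosinor.csv", index=False)

    summary = {"groups": {g: {"n": d[3]} for g, d in designs.items()}, "organs": {}}
    comp_rows = []
    ref_group = next(iter(designs))
    for organ in ORGANS:
        organ_sum = {}
        ref_mean = circ.circ_mean(
            [f.acrophase_zt for f in fits[organ][ref_group]]
        )
        data = {}
        for group, gfits in fits[organ].items():
            ga = group_acrophase(gfits)
            organ_sum[group] = {
                "acrophase_mean_zt": ga.mean_zt,
                "acrophase_sem_h": ga.sem,
                "n_arrhythmic": ga.n_arrhythmic,
            }
            # unwrap to the reference group's phase for linear testing
            data[group] = circ.signed_diff(
                [f.acrophase_zt for f in gfits], ref_mean
            ).tolist()
        res = compare_groups(data)
        organ_sum["test"] = _comparison_summary(res)
        comp_rows += _comparison_rows(organ, res)
        summary["organs"][organ] = organ_sum
    pd.DataFrame(comp_rows).to_csv(out_dir / "comparisons.csv", index=False)

    if make_plots:
        _waveform_figure(df, out_dir)
    return summary


def _waveform_figure(df: pd.DataFrame, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(ORGANS), figsize=(4 * len(ORGANS), 3.2),
                             sharey=True)
    for ax, organ in zip(np.atleast_1d(axes), ORGANS):
        sub = df[df["organ"] == organ]
        for group, grp in sub.groupby("group"):
            ax.errorbar(
                range(len(grp)), grp["acrophase_zt"], fmt="o", label=group,
                alpha=0.7,
            )
        ax.set_title(organ)
        ax.set_ylabel("acrophase (ZT h)")
    np.atleast_1d(axes)[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_dir / "acrophases.png", dpi=110)
    plt.close(fig)


def run_experiment(
    exp_id: str,
    out_dir,
    seed: int = 0,
    config: Optional[dict] = None,
    make_plots: bool = True,
) -> dict:
    """Run one of the six synthetic experiment reproductions.

    Returns the summary dict (also written to ``out_dir/summary.json``).
    ``config`` may override cohort sizes via ``n_per_group``.
    """
    if exp_id not in EXPERIMENTS:
        raise InvalidArgumentError(
            f"unknown experiment {exp_id!r}; choose from {EXPERIMENTS}"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = config or {}
    n_over = config.get("n_per_group", {})

    def nn(group, default):
        return int(n_over.get(group, default))

    if exp_id in ("exp1", "exp3"):
        diet = "ND" if exp_id == "exp1" else "HFD"
        n_nw, n_w = (5, 9) if exp_id == "exp1" else (10, 8)
        presets = {
            f"{diet}_NoWheel": (f"{diet}_NoWheel", nn(f"{diet}_NoWheel", n_nw)),
            f"{diet}_Wheel": (f"{diet}_Wheel", nn(f"{diet}_Wheel", n_w)),
        }
        summary = _sjl_behavior_experiment(presets, seed, out_dir, make_plots)
    elif exp_id in ("exp2", "exp4"):
        diet = "ND" if exp_id == "exp2" else "HFD"
        n_ctl, n_sjl, n_sw = (6, 7, 6) if exp_id == "exp2" else (6, 6, 6)
        sjl = make_sjl(7, 6.0, 5)
        ld = make_ld(sjl.n_days)
        designs = {
            "control": (ld, preset(f"{diet}_NoWheel"), False, nn("control", n_ctl)),
            "SJL": (sjl, preset(f"{diet}_NoWheel"), False, nn("SJL", n_sjl)),
            "SJL_Wheel": (sjl, preset(f"{diet}_Wheel"), True, nn("SJL_Wheel", n_sw)),
        }
        summary = _biolum_experiment(designs, seed, out_dir, make_plots, THURSDAY)
        summary["measurement_day"] = THURSDAY
    elif exp_id == "exp5":
        adv = make_advance(7, 6.0, 7)
        designs = {
            "NoWheel": (adv, preset("ND_NoWheel"), False, nn("NoWheel", 6)),
            "Wheel": (adv, preset("ND_Wheel"), True, nn("Wheel", 6)),
        }
        summary = _biolum_experiment(
            designs, seed, out_dir, make_plots, ADVANCE_MEASURE_DAY
        )
        summary["measurement_day"] = ADVANCE_MEASURE_DAY
    else:  # exp6
        cohorts = {
            "NoWheel": ("ND_NoWheel", nn("NoWheel", 9)),
            "Wheel": ("ND_Wheel", nn("Wheel", 7)),
        }
        summary = {"schedule": "DD 10 days", "groups": {}}
        data, rows = {}, []
        for gi, (group, (pname, n)) in enumerate(cohorts.items()):
            periods = []
            for a in range(n):
                rng = _rng(seed, gi, a)
                rec = simulate_activity(
                    make_dd(10), preset(pname), rng=rng,
                    animal_id=f"{group}_{a + 1:02d}",
                )
                res = chi_squared_periodogram(rec)
                periods.append(res.best_period)
                rows.append(
                    {
                        "group": group,
                        "animal_id": rec.animal_id,
                        "best_period_h": res.best_period,
                        "significant": res.significant,
                    }
                )
                if a == 0 and make_plots:
                    _save_periodogram_fig(res, out_dir, group)
                if a == 0:
                    pd.DataFrame(
                        {
                            "period_h": res.periods,
                            "q": res.q_stat,
                            "sig_line": res.significance_line,
                        }
                    ).to_csv(out_dir / f"periodogram_{group}.csv", index=False)
            arr = np.array(periods)
            summary["groups"][group] = {
                "n": n,
                "best_period_mean_h": float(arr.mean()),
                "best_period_sem_h": float(arr.std(ddof=1) / np.sqrt(n)),
            }
            data[group] = periods
        pd.DataFrame(rows).to_csv(out_dir / "periods.csv", index=False)
        res = compare_groups(data)
        summary["tests"] = {"free_running_period": _comparison_summary(res)}
        pd.DataFrame(_comparison_rows("free_running_period", res)).to_csv(
            out_dir / "comparisons.csv", index=False
        )

    summary["experiment"] = exp_id
    summary["seed"] = int(seed)
    _write_summary(summary, out_dir)
    return summary
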