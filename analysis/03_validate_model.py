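"""Validate the selected model: per-winter regression checks on the
training seasons and genuine prediction on the held-out winter, with 95%
confidence/prediction bands, coverage counts and correlation metrics.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from chillqy import (
    CUConfig,
    ModelFit,
    assemble_design,
    compute_cu,
    coverage_count,
    predict_with_intervals,
    prediction_metrics,
    read_climate_csv,
    read_qy_csv,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    series = read_climate_csv(args.outdir / "climate.csv")["home"]
    obs = read_qy_csv(args.outdir / "qy.csv")
    best_d = json.loads((args.outdir / "best_model.json").read_text())
    config = CUConfig(best_d["cu_type"], best_d["temp_stat"],
                      best_d["threshold"], best_d["window"])
    fit = ModelFit(config=config, a=best_d["a"], b=best_d["b"],
                   sigma=best_d["sigma"], n_obs=best_d["n_obs"],
                   log_lik=best_d["log_lik"], aic=best_d["aic"],
                   r_squared=best_d["r_squared"])

    cu = compute_cu(series, config)
    last_season = obs["date"].max().year - 1
    train = obs[obs["date"] <= pd.Timestamp(last_season, 3, 31)]
    train_design = assemble_design(cu, train)

    rows, points = [], []
    seasons = sorted(obs["date"].dt.year.where(
        obs["date"].dt.month >= 7, obs["date"].dt.year - 1).unique())
    for season in seasons:
        sel = obs[(obs["date"] >= pd.Timestamp(season, 7, 1))
                  & (obs["date"] <= pd.Timestamp(season + 1, 6, 30))]
        design = assemble_design(cu, sel)
        preds = predict_with_intervals(
            fit, design["cu"], train_design, dates=design["date"]
        ).drop_duplicates("date")
        qy_obs = sel.groupby(["line", "date"], as_index=False)["qy"].mean()
        n_ci, n_tot = coverage_count(preds, qy_obs[["date", "qy"]], "confidence")
        n_pi, _ = coverage_count(preds, qy_obs[["date", "qy"]], "prediction")
        merged = qy_obs.merge(preds, on="date")
        r, r2 = prediction_metrics(merged["qy_hat"], merged["qy"], scale="logit")
        role = "held-out" if season == last_season else "training"
        rows.append({"season": f"{season}-{season+1}", "role": role,
                     "n_points": n_tot, "n_within_ci": n_ci,
                     "n_within_pi": n_pi,
                     "pearson_r": r, "r_squared_pred": r2})
        merged.insert(0, "season", f"{season}-{season+1}")
        points.append(merged)

    report = pd.DataFrame(rows)
    report.to_csv(args.outdir / "validation_summary.csv", index=False)
    pd.concat(points, ignore_index=True).to_csv(
        args.outdir / "validation_points.csv", index=False)

    total = report[report.role == "training"][
        ["n_within_ci", "n_within_pi", "n_points"]].sum()
    held = report[report.role == "held-out"].iloc[0]
    print(report.to_string(index=False,
                           float_format=lambda v: f"{v:.3f}"))
    print(f"training winters: {total['n_within_pi']} of {total['n_points']} "
          f"points inside the 95% prediction band "
          f"({total['n_within_ci']} inside the narrow mean-response band)")
    print(f"held-out winter {held['season']}: {held['n_within_pi']} of "
          f"{held['n_points']} inside the prediction band; "
          f"r={held['pearson_r']:.2f}, R^2={held['r_squared_pred']:.2f}")


if __name__ == "__main__":
    main()
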