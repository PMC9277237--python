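"""Orchestration: simulate or load tables, build indices, analyse, report.

The central product is the *index table*: one row per inflorescence
joining the visitation flags, the Visit Lateness Index, and the seed
indices (s, SLI, w). The three inferential results — the two-group
seed-set model under both visitor definitions, their AIC comparison, and
the weighted VLI->SLI regression — are computed from it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import DegenerateDataError
from .inference import compare_visitor_definitions, sli_vli_regression
from .phenology import compute_vli, cover_series
from .seeds import seed_summaries
from .simulate import SimulationConfig, simulate_season
from .tables import TableBundle, read_tables, write_tables
from .visitation import (
    cooccurrence_test,
    count_visit_images,
    diel_histogram,
    image_fraction_pct,
    visitation_flags,
)

__all__ = ["build_index_table", "analyze_bundle", "run_pipeline", "format_report_text"]


def build_index_table(bundle: TableBundle, seed_level_sli: bool = False) -> pd.DataFrame:
    """One row per inflorescence: flags, n_visit_images, vli, s, sli, w.

    Inflorescences without dissection records get NaN seed columns; those
    never seen visited get NaN vli. ``fully_recorded`` is carried through
    for downstream restriction.
    """
    flags = visitation_flags(bundle.visits, bundle.phenology)
    vli = compute_vli(bundle.visits, bundle.phenology)
    seeds = seed_summaries(bundle.dissection, seed_level=seed_level_sli)
    idx = flags.join(vli[["peak_doy", "mean_visit_doy", "vli"]]).join(seeds)
    rec = bundle.phenology.set_index("inflorescence_id")["fully_recorded"]
    idx["fully_recorded"] = rec.reindex(idx.index)
    return idx


def analyze_bundle(
    bundle: TableBundle,
    bin_width_min: int = 60,
    yates: bool = False,
    seed_level_sli: bool = False,
) -> dict:
    """Run the full analysis on a validated bundle; returns a report dict.

    Sections that the data cannot support (no visits, degenerate 2x2
    table, too few index rows) are reported as ``None`` with a note
    rather than aborting the run.
    """
    report: dict = {"n_frames": int(len(bundle.frames)), "notes": []}

    counts = count_visit_images(bundle.visits)
    n_visit_images = int(counts["count"].sum())
    report["visit_images"] = {
        "total": n_visit_images,
        "pct_of_frames": (
            image_fraction_pct(n_visit_images, len(bundle.frames), sig=2)
            if len(bundle.frames)
            else None
        ),
        "by_taxon": {
            t: {"count": int(row["count"]),
                "share_pct": None if pd.isna(row["share_pct"]) else int(row["share_pct"])}
            for t, row in counts.iterrows()
        },
    }

    idx = build_index_table(bundle, seed_level_sli=seed_level_sli)
    report["n_inflorescences"] = int(len(idx))
    report["n_visited_any"] = int(idx["visited_any"].sum())

    diel = diel_histogram(bundle.visits, bundle.frames, bin_width_min)
    curve, peak_cover_doy = cover_series(bundle.cover)
    report["peak_cover_doy"] = peak_cover_doy

    try:
        co = cooccurrence_test(idx, yates=yates)
        report["cooccurrence"] = {
            "chi2": co.statistic, "df": co.df, "p": co.p_value,
            "table": co.table.to_numpy().tolist(),
        }
    except DegenerateDataError as exc:
        report["cooccurrence"] = None
        report["notes"].append(f"cooccurrence: {exc}")

    try:
        cmp = compare_visitor_definitions(idx)
        report["two_group"] = {
            "any_visit": asdict(cmp["any_visit"]),
            "bumblebee_only": asdict(cmp["bumblebee_only"]),
            "delta_aic": cmp["delta_aic"],
        }
    except DegenerateDataError as exc:
        report["two_group"] = None
        report["notes"].append(f"two_group: {exc}")

    for key, weighted in (("sli_vli_weighted", True), ("sli_vli_unweighted", False)):
        try:
            report[key] = asdict(sli_vli_regression(idx, weighted=weighted))
        except DegenerateDataError as exc:
            report[key] = None
            report["notes"].append(f"{key}: {exc}")

    report["_tables"] = {"index": idx, "diel": diel.table, "cover_curve": curve}
    return report


def _fmt_p(p: float) -> str:
    return f"{p:.3g}"


def format_report_text(report: dict) -> str:
    """Plain-text results paragraph with the run's computed numbers."""
    lines = []
    vi = report["visit_images"]
    frac = vi["pct_of_frames"]
    lines.append(
        f"Across {report['n_frames']} images, {vi['total']}"
        + (f" ({frac:.3g}%)" if frac is not None else "")
        + " captured foraging pollinators."
    )
    lines.append(
        f"Of {report['n_inflorescences']} recorded inflorescences, "
        f"{report['n_visited_any']} were visited on camera."
    )
    by = vi["by_taxon"]
    if vi["total"]:
        lines.append(
            f"Moths provided {by['moth']['share_pct']}% of visits "
            f"({by['moth']['count']}) while bumblebees provided "
            f"{by['bumblebee']['share_pct']}% ({by['bumblebee']['count']})."
        )
    if report.get("cooccurrence"):
        co = report["cooccurrence"]
        lines.append(
            f"Bumblebee x moth visitation association: chi2 = {co['chi2']:.3f}, "
            f"d.f. = {co['df']}, p = {_fmt_p(co['p'])}."
        )
    if report.get("two_group"):
        tg = report["two_group"]
        a, b = tg["any_visit"], tg["bumblebee_only"]
        lines.append(
            f"Visited inflorescences (any class) had {a['mean_difference_pct']:.1f}% "
            f"higher seed set than unvisited (F_1,{a['df'][1]} = {a['F']:.2f}, "
            f"p = {_fmt_p(a['p_value'])}, R2 = {a['r_squared']:.3f})."
        )
        lines.append(
            f"Bumblebee-only grouping: F_1,{b['df'][1]} = {b['F']:.2f}, "
            f"p = {_fmt_p(b['p_value'])}, R2 = {b['r_squared']:.3f}; "
            f"dAIC = {tg['delta_aic']:.2f} favouring the all-visitor definition."
            if tg["delta_aic"] >= 0 else
            f"Bumblebee-only grouping: F_1,{b['df'][1]} = {b['F']:.2f}, "
            f"p = {_fmt_p(b['p_value'])}, R2 = {b['r_squared']:.3f}; "
            f"dAIC = {tg['delta_aic']:.2f} favouring the bumblebee-only definition."
        )
    if report.get("sli_vli_weighted"):
        w = report["sli_vli_weighted"]
        lines.append(
            f"Weighted SLI~VLI regression: slope = {w['slope']:.2f} per day, "
            f"d.f. = {w['df_residual']}, F = {w['F']:.2f}, "
            f"p = {_fmt_p(w['p_value'])}, R2 = {w['r_squared']:.3f}."
        )
    if report.get("sli_vli_unweighted"):
        u = report["sli_vli_unweighted"]
        lines.append(f"Unweighted regression: p = {_fmt_p(u['p_value'])}.")
    for note in report["notes"]:
        lines.append(f"[undefined] {note}")
    return "\n".join(lines)


def _figures(report: dict, bundle: TableBundle, out: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .tables import fractional_doy

    paths = []
    idx = report["_tables"]["index"]

    # season summary: visit DOY histogram by taxon + cover curve
    fig, ax = plt.subplots(figsize=(7, 3.5))
    curve = report["_tables"]["cover_curve"]
    if len(bundle.visits):
        doys = fractional_doy(bundle.visits["timestamp"])
        bins = np.arange(np.floor(doys.min()), np.ceil(doys.max()) + 2)
        bottom = np.zeros(len(bins) - 1)
        for taxon, color in (("moth", "#1b2a62"), ("bumblebee", "#4169c8"), ("other", "#a9c4eb")):
            h, _ = np.histogram(doys[bundle.visits["taxon"] == taxon], bins=bins)
            ax.bar(bins[:-1], h, bottom=bottom, width=1, align="edge", color=color, label=taxon)
            bottom += h
    ax2 = ax.twinx()
    ax2.plot(curve["doy"], curve["mean_cover"], color="#d4508c", label="cover")
    ax.set_xlabel("day of year")
    ax.set_ylabel("visit images")
    ax2.set_ylabel("mean floral cover")
    ax.legend(loc="upper left", fontsize=8)
    paths.append(out / "season_summary.svg")
    fig.savefig(paths[-1], bbox_inches="tight")
    plt.close(fig)

    # diel histogram of visit rate
    diel = report["_tables"]["diel"]
    fig, ax = plt.subplots(figsize=(7, 3))
    ax.bar(diel["bin_start_min"] / 60, diel["rate"], width=diel["bin_start_min"].diff().iloc[-1] / 60
           if len(diel) > 1 else 1, align="edge", color="#1b2a62")
    ax.set_xlabel("hour of day")
    ax.set_ylabel("visit images per frame")
    paths.append(out / "diel_histogram.svg")
    fig.savefig(paths[-1], bbox_inches="tight")
    plt.close(fig)

    # grouped seed set + VLI->SLI scatter
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.5))
    sub = idx[idx["s"].notna()]
    groups = [sub.loc[~sub["visited_any"], "s"], sub.loc[sub["visited_any"], "s"]]
    axes[0].boxplot(groups, tick_labels=["unvisited", "visited"])
    axes[0].set_ylabel("seed set s")
    reg = sub[sub["vli"].notna() & sub["sli"].notna()]
    axes[1].scatter(reg["vli"], reg["sli"], s=8 + 300 * reg["w"], c="#444444", alpha=0.7)
    fit = report.get("sli_vli_weighted")
    if fit and len(reg):
        xx = np.linspace(reg["vli"].min(), reg["vli"].max(), 20)
        axes[1].plot(xx, fit["intercept"] + fit["slope"] * xx, "k--")
    axes[1].set_xlabel("VLI (days)")
    axes[1].set_ylabel("SLI (percentile)")
    paths.append(out / "seedset_and_lateness.svg")
    fig.savefig(paths[-1], bbox_inches="tight")
    plt.close(fig)
    return paths


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items() if not k.startswith("_")}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    return obj


def run_pipeline(
    out_dir: str | Path,
    input_dir: str | Path | None = None,
    sim_config: SimulationConfig | None = None,
    seed: int | None = None,
    bin_width_min: int = 60,
    yates: bool = False,
    figures: bool = True,
) -> dict:
    """simulate-or-load -> index -> analyse -> report + figures + manifest.

    Either ``input_dir`` (the five CSVs) or ``sim_config`` must be given.
    Writes index/diel/cover CSVs, ``analysis_report.json``,
    ``report.txt``, SVG figures, and ``manifest.json`` with a checksum of
    every output. Deterministic given inputs and seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if input_dir is not None:
        bundle = read_tables(input_dir)
        source = {"input_dir": str(input_dir)}
    else:
        cfg = sim_config or SimulationConfig()
        bundle, truth = simulate_season(cfg, seed=seed)
        sim_dir = out / "simulated"
        written += list(write_tables(bundle, sim_dir).values())
        truth.visits.to_csv(sim_dir / "ground_truth_visits.csv", index=False)
        truth.florets.to_csv(sim_dir / "ground_truth_florets.csv", index=False)
        written += [sim_dir / "ground_truth_visits.csv", sim_dir / "ground_truth_florets.csv"]
        cfg_json = {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg).items()}
        source = {"simulated": True, "config": cfg_json, "seed": seed,
                  "config_sha256": hashlib.sha256(
                      json.dumps(cfg_json, sort_keys=True).encode()).hexdigest()}

    report = analyze_bundle(bundle, bin_width_min=bin_width_min, yates=yates)

    tables = report["_tables"]
    tables["index"].to_csv(out / "index_table.csv")
    tables["diel"].to_csv(out / "diel.csv", index=False)
    tables["cover_curve"].to_csv(out / "cover_curve.csv", index=False)
    written += [out / "index_table.csv", out / "diel.csv", out / "cover_curve.csv"]

    (out / "analysis_report.json").write_text(
        json.dumps(_jsonable(report), indent=2, sort_keys=True) + "\n"
    )
    (out / "report.txt").write_text(format_report_text(report) + "\n")
    written += [out / "analysis_report.json", out / "report.txt"]

    if figures:
        written += _figures(report, bundle, out)

    manifest = {
        "tool": "cloverwatch",
        "version": __version__,
        "source": source,
        "row_counts": {name: int(len(getattr(bundle, name)))
                       for name in ("frames", "visits", "phenology", "dissection", "cover")},
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in written},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    report["manifest"] = manifest
    return report
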