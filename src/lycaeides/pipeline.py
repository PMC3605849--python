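"""Pipeline orchestration: configured stages over the library, with a
machine-readable run manifest.

A run configuration is a plain mapping (loadable from YAML or JSON) with an
experiment ``kind`` (simulate / fit-preference / fit-diapause / morphospace /
mate-odds / distances), input paths, sampler settings, permutation counts and
an output directory. Every output directory receives a ``manifest.json``
recording the package version, seeds, defaults that filled unspecified
settings, and the design-decision flags (KL direction, pairing log-odds form,
Mantel sidedness), so results are reproducible byte-for-byte from
(config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import io as lio
from .diagnostics import gelman_rubin, summarize
from .diapause_model import fit_diapause_glm, fit_hatch_dia
from .distance_analysis import mantel, mrm, partial_mantel
from .errors import InvalidInputError
from .mate_choice import conspecific_log_odds, fit_approach_preference
from .morphospace import kl_permutation_test
from .preference_model import compare_dic, dic_detail, fit_preference, fit_preference_constrained
from .synthetic_data import gen_distance_system, gen_egg_counts

__all__ = ["run_pipeline", "DEFAULTS"]

DEFAULTS = {
    "n_chains": 2,
    "n_iter": 50_000,
    "burn_in": 5_000,
    "seed": 0,
    "w_max": 1e4,
    "n_perm": 10_000,
    "n_reps": 1000,
    "alternative": "greater",
    "kl_direction": "approached_vs_presented",
    "log_odds_form": "sum",
}


def _settings(config: dict) -> tuple[dict, list[str]]:
    merged = dict(DEFAULTS)
    filled = [k for k in DEFAULTS if k not in config]
    merged.update({k: config[k] for k in config if k in DEFAULTS})
    return merged, filled


def _write_manifest(outdir: Path, kind: str, settings: dict, filled: list[str], extra: dict) -> None:
    from importlib.metadata import version

    try:
        ver = version("lycaeides")
    except Exception:  # editable/dev tree without metadata
        ver = "unknown"
    manifest = {
        "package_version": ver,
        "kind": kind,
        "settings": settings,
        "defaults_used_for": sorted(filled),
        **extra,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def run_pipeline(config: dict) -> Path:
    """Execute one configured stage; returns the output directory."""
    kind = config.get("kind")
    if kind is None:
        raise InvalidInputError("config needs a 'kind'")
    outdir = Path(config.get("output_dir", "results"))
    outdir.mkdir(parents=True, exist_ok=True)
    settings, filled = _settings(config)
    seed = int(settings["seed"])

    if kind == "simulate":
        table, truth = gen_egg_counts(
            pi=np.asarray(config.get("pi", [0.7, 0.3]), dtype=float),
            w=float(config.get("w", 10.0)),
            n_females=int(config.get("n_females", 20)),
            egg_mean=float(config.get("egg_mean", 20.0)),
            seed=seed,
            population_id=str(config.get("population", "synthetic")),
        )
        lio.write_egg_counts(table, outdir / "egg_counts.csv")
        (outdir / "truth.json").write_text(json.dumps(dataclasses.asdict(truth), indent=2))
        _write_manifest(outdir, kind, settings, filled, {})
        return outdir

    if kind == "fit-preference":
        tables = lio.read_egg_counts(config["input"])
        compare = bool(config.get("compare_constrained", False))
        for pop, table in tables.items():
            post = fit_preference(table, n_chains=int(settings["n_chains"]),
                                  n_iter=int(settings["n_iter"]),
                                  burn_in=int(settings["burn_in"]), seed=seed,
                                  w_max=float(settings["w_max"]))
            lio.write_posterior_summary(post.summary(), outdir / f"{pop}_summary.csv")
            lio.write_draws(
                np.column_stack([post.pooled_pi(), post.pooled_w()[:, None]]),
                [f"pi[{c}]" for c in table.category_labels] + ["w"],
                outdir / f"{pop}_draws.csv",
            )
            if compare:
                con = fit_preference_constrained(
                    table, n_chains=int(settings["n_chains"]),
                    n_iter=int(settings["n_iter"]),
                    burn_in=int(settings["burn_in"]), seed=seed,
                    w_max=float(settings["w_max"]))
                res = compare_dic(dic_detail(post, table).dic, dic_detail(con, table).dic)
                (outdir / f"{pop}_dic.json").write_text(
                    json.dumps(dataclasses.asdict(res), indent=2))
        _write_manifest(outdir, kind, settings, filled, {"populations": list(tables)})
        return outdir

    if kind == "fit-diapause":
        tables = lio.read_hatch_table(config["input"])
        model = str(config.get("model", "glm"))
        for pop, table in tables.items():
            if model == "dia":
                post = fit_hatch_dia(table, n_chains=int(settings["n_chains"]),
                                     n_iter=int(settings["n_iter"]),
                                     burn_in=int(settings["burn_in"]), seed=seed)
                lio.write_posterior_summary(post.summary(), outdir / f"{pop}_summary.csv")
            else:
                post = fit_diapause_glm(table, n_chains=max(int(settings["n_chains"]), 2),
                                        n_iter=int(settings["n_iter"]),
                                        burn_in=int(settings["burn_in"]), seed=seed)
                import pandas as pd

                rows = []
                for k, t in enumerate(post.treatments):
                    med, lo, hi = summarize(post.alpha_samples[..., k])
                    rows.append((f"alpha[{t}]", med, lo, hi,
                                 gelman_rubin(post.alpha_samples[..., k])))
                lio.write_posterior_summary(
                    pd.DataFrame(rows, columns=["parameter", "median", "etpi_2.5",
                                                "etpi_97.5", "rhat"]),
                    outdir / f"{pop}_summary.csv")
        _write_manifest(outdir, kind, settings, filled,
                        {"populations": list(tables), "model": model})
        return outdir

    if kind == "morphospace":
        scores = lio.read_model_scores(config["scores"])
        trials = lio.read_trials(config["trials"])
        res = kl_permutation_test(trials, scores, n_reps=int(settings["n_reps"]), seed=seed)
        (outdir / "kl_result.json").write_text(json.dumps({
            "d_kl": res.d_kl, "p_value": res.p_value, "n_reps": res.n_reps,
            "mode": res.mode, "direction": res.direction, "seed": res.seed,
        }, indent=2))
        _write_manifest(outdir, kind, settings, filled, {})
        return outdir

    if kind == "mate-odds":
        import pandas as pd

        df = pd.read_csv(config["input"])
        for c in ("population", "approaches_idas", "approaches_melissa"):
            if c not in df.columns:
                raise InvalidInputError(f"mate-odds input missing column {c!r}")
        posts = {}
        rows = []
        for pop, sub in df.groupby("population", sort=False):
            post = fit_approach_preference(
                sub["approaches_idas"].to_numpy(), sub["approaches_melissa"].to_numpy(),
                n_chains=int(settings["n_chains"]), n_iter=int(settings["n_iter"]),
                burn_in=int(settings["burn_in"]), seed=seed)
            posts[str(pop)] = post.pooled_pi()[:, 0]
            med, lo, hi = summarize(posts[str(pop)])
            rows.append((str(pop), med, lo, hi))
        pd.DataFrame(rows, columns=["population", "median", "etpi_2.5", "etpi_97.5"]) \
            .to_csv(outdir / "approach_preference.csv", index=False)
        pairs = config.get("pairs", [])
        odds_rows = []
        for ida, mel in pairs:
            lo_draws = conspecific_log_odds(posts[ida], posts[mel],
                                            form=str(settings["log_odds_form"]))
            med, lo, hi = summarize(lo_draws)
            odds_rows.append((ida, mel, med, lo, hi))
        if odds_rows:
            pd.DataFrame(odds_rows, columns=["idas_population", "melissa_population",
                                             "median", "etpi_2.5", "etpi_97.5"]) \
                .to_csv(outdir / "pairing_log_odds.csv", index=False)
        _write_manifest(outdir, kind, settings, filled,
                        {"form": settings["log_odds_form"]})
        return outdir

    if kind == "distances":
        if "genetic" in config:
            G = lio.read_distance_matrix(config["genetic"], kind="genetic_F")
            Z = lio.read_distance_matrix(config["geographic"], kind="geographic")
            P = {name: lio.read_distance_matrix(p, kind=f"phenotypic:{name}")
                 for name, p in config.get("phenotypic", {}).items()}
        else:  # synthetic system
            sys_ = gen_distance_system(n_pops=int(config.get("n_pops", 10)), seed=seed)
            G, Z, P = sys_.genetic, sys_.geographic, sys_.phenotypic
        n_perm = int(settings["n_perm"])
        alt = str(settings["alternative"])
        out = {"mantel_geo": dataclasses.asdict(
            mantel(G, Z, n_perm=n_perm, seed=seed, alternative=alt))}
        for name, Pm in P.items():
            out[f"partial_mantel_{name}"] = dataclasses.asdict(
                partial_mantel(G, Pm, Z, n_perm=n_perm, seed=seed, alternative=alt))
        res = mrm(G, [Z] + list(P.values()), n_perm=n_perm, seed=seed,
                  names=["geographic"] + list(P))
        out["mrm"] = dataclasses.asdict(res)
        (outdir / "distance_results.json").write_text(
            json.dumps(out, indent=2, default=lambda o: np.asarray(o).tolist()))
        _write_manifest(outdir, kind, settings, filled, {"alternative": alt})
        return outdir

    raise InvalidInputError(f"unknown pipeline kind {kind!r}")
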