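"""End-to-end orchestration: simulate → cohort → label → fit → network → regress.

One :class:`PipelineConfig` drives every stage; a single global seed is
fanned out deterministically to per-stage seeds (stable hash of the
stage name) so any stage can be re-run in isolation. Artifacts are
written as plain-text tables/JSON under an output directory, and the
report (Markdown + JSON) is stamped with the configuration hash and
seed, so identical configurations yield identical reports.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as spio
from .categories import CATEGORIES
from .cohort import CohortConfig, build_profiles, match_cancer_queries, partition_severity
from .heavytail import distribution_median, fit_loglog_slope
from .hmm import select_num_states, signature_states, stability_ranking, train_hmm
from .regression import disease_frequency_records, incidence_regression
from .social import (
    category_preference_contrast,
    enrichment_vs_chance,
    find_pairs,
    lag_duration_contrasts,
    overlap_stats,
)
from .synth import SyntheticConfig, realized_degrees, simulate_log

_STAGES = ("simulate", "cohort", "heavytail", "statehmm", "social", "regress")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.blake2b(f"{global_seed}:{stage}".encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2**31 - 1)


@dataclass
class PipelineConfig:
    out_dir: str = "seekpaths_run"
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    hmm_K: int = 5
    candidate_Ks: tuple[int, ...] = (3, 4, 5, 6)
    n_restarts: int = 5
    train_fraction: float = 0.75
    run_selection: bool = True
    n_permutations: int = 1000
    use_text_matching: bool = True

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "seed": self.seed,
                "synthetic": self.synthetic.to_json(),
                "cohort": [self.cohort.min_pages, self.cohort.min_categories],
                "hmm_K": self.hmm_K,
                "candidate_Ks": list(self.candidate_Ks),
                "n_restarts": self.n_restarts,
                "train_fraction": self.train_fraction,
                "run_selection": self.run_selection,
                "n_permutations": self.n_permutations,
                "use_text_matching": self.use_text_matching,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages in dependency order and write a stamped report.

    Any stage failure raises ``RuntimeError`` naming the stage; artifacts
    from completed stages are retained in ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    state: dict = {}
    for stage in _STAGES:
        try:
            _run_stage(stage, config, state, report, out)
        except Exception as exc:  # noqa: BLE001 - stage attribution
            _write_report(report, out)
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    _write_report(report, out)
    return report


def _run_stage(stage: str, config: PipelineConfig, state: dict, report: dict, out: Path):
    seed = stage_seed(config.seed, stage)
    if stage == "simulate":
        syn = config.synthetic.with_seed(stage_seed(config.seed, "simulate"))
        events, contacts, lexicon = simulate_log(syn)
        spio.write_query_log(events, out / "query_log.tsv")
        spio.write_contacts(contacts, out / "contacts.tsv")
        spio.write_lexicon(lexicon, out / "lexicon.csv")
        state.update(events=events, contacts=contacts, lexicon=lexicon, synthetic=syn)
        report["stages"]["simulate"] = {
            "n_users": syn.n_users,
            "n_events": int(len(events)),
            "n_edges": int(len(contacts)),
        }
    elif stage == "cohort":
        lex = partition_severity(state["lexicon"])
        events = state["events"]
        if config.use_text_matching and len(events):
            events = match_cancer_queries(events.drop(columns=["cancers"]), lex)
        profiles, tally = build_profiles(events, lex, config.cohort)
        spio.write_profiles(profiles, out / "profiles.tsv")
        spio.write_json(tally, out / "exclusion_tally.json")
        state.update(profiles=profiles, lexicon_sev=lex)
        report["stages"]["cohort"] = tally
    elif stage == "heavytail":
        events, profiles = state["events"], state["profiles"]
        fits = {}
        if len(events):
            pages_per_user = events.groupby("user_id").size().to_numpy()
            users_per_page = events.groupby("page_id")["user_id"].nunique().to_numpy()
            fits["pages_per_user"] = fit_loglog_slope(pages_per_user).as_dict()
            fits["users_per_page"] = fit_loglog_slope(users_per_page).as_dict()
        contacts = state["contacts"]
        if len(contacts):
            edges = contacts.to_numpy()
            deg = realized_degrees(edges, int(edges.max()) + 1)
            deg = deg[deg > 0]
            fits["contact_degree"] = fit_loglog_slope(deg).as_dict()
            fits["contact_degree"]["median"] = distribution_median(deg)
        spio.write_json(fits, out / "powerlaw_fits.json")
        report["stages"]["heavytail"] = fits
    elif stage == "statehmm":
        profiles = state["profiles"]
        res: dict = {"per_severity": {}}
        if len(profiles) >= 8:
            # the two severity groups are modelled separately (each is one
            # journey regime); selection runs within each stratum
            rows = []
            for sev in ("aggressive", "indolent"):
                sub = profiles.loc[profiles["severity"] == sev, "category_sequence"]
                if len(sub) < 8:
                    res["per_severity"][sev] = {"skipped": True, "n_users": int(len(sub))}
                    continue
                seqs = sub.tolist()
                if config.run_selection:
                    sel = select_num_states(
                        seqs,
                        config.candidate_Ks,
                        train_fraction=config.train_fraction,
                        n_restarts=config.n_restarts,
                        seed=stage_seed(config.seed, f"select-{sev}"),
                    )
                    K = sel.best_K
                    selection = {
                        "candidate_Ks": sel.candidate_Ks,
                        "error_curve": sel.error_curve(),
                        "best_K": sel.best_K,
                    }
                    rows += [(sev, k, e) for k, e in sel.error_curve()]
                else:
                    K = config.hmm_K
                    selection = None
                model, history = train_hmm(
                    seqs, K, seed=stage_seed(config.seed, f"hmm-{sev}")
                )
                spio.write_model(model, out / f"hmm_{sev}.json")
                res["per_severity"][sev] = {
                    "n_users": int(len(sub)),
                    "K": K,
                    "final_loglik": history[-1],
                    "selection": selection,
                    "signature": signature_states(model),
                    "stability": stability_ranking(model),
                }
            if rows:
                pd.DataFrame(rows, columns=["severity", "K", "holdout_error"]).to_csv(
                    out / "selection_errors.tsv", sep="\t", index=False
                )
        else:
            res["skipped"] = True
        spio.write_json(_jsonable(res), out / "statehmm.json")
        report["stages"]["statehmm"] = _jsonable(res)
    elif stage == "social":
        profiles, contacts = state["profiles"], state["contacts"]
        res = {}
        if len(profiles) and len(contacts):
            edges = contacts.to_numpy()
            pairs = find_pairs(profiles, edges)
            pairs.to_csv(out / "pairs.tsv", sep="\t", index=False)
            res["n_pairs"] = int(len(pairs))
            if len(pairs):
                res["enrichment"] = enrichment_vs_chance(
                    len(pairs), profiles, edges,
                    n_permutations=config.n_permutations, seed=seed,
                )
                res["overlap"] = overlap_stats(pairs, profiles, seed=seed)
                res["lag_duration"] = lag_duration_contrasts(pairs)
                res["category_preference"] = category_preference_contrast(pairs)
        else:
            res["skipped"] = True
            res["n_pairs"] = 0
        spio.write_json(_jsonable(res), out / "social_stats.json")
        report["stages"]["social"] = _jsonable(res)
    elif stage == "regress":
        profiles, lex = state["profiles"], state.get("lexicon_sev", state["lexicon"])
        res = {}
        if len(profiles) >= 5:
            records = disease_frequency_records(profiles, lex)
            res = incidence_regression(records)
        else:
            res["skipped"] = True
        spio.write_json(_jsonable(res), out / "regression.json")
        report["stages"]["regress"] = _jsonable(res)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _write_report(report: dict, out: Path) -> None:
    spio.write_json(_jsonable(report), out / "report.json")
    lines = [
        "# seekpaths pipeline report",
        "",
        f"- config hash: `{report['config_hash']}`",
        f"- seed: {report['seed']}",
        "",
    ]
    st = report["stages"]
    if "cohort" in st:
        t = st["cohort"]
        lines += [
            "## Cohort",
            f"- users screened: {t.get('n_users_total')}",
            f"- excluded at page gate: {t.get('n_excluded_page_gate')}",
            f"- excluded at category gate: {t.get('n_excluded_category_gate')}",
            f"- included: {t.get('n_included')}",
            "",
        ]
    if "heavytail" in st:
        lines.append("## Power-law fits")
        for name, fit in st["heavytail"].items():
            if isinstance(fit, dict) and "slope" in fit:
                med = f", median {fit['median']}" if "median" in fit else ""
                lines.append(f"- {name}: slope {fit['slope']:.3f} (R² {fit['r2']:.3f}{med})")
        lines.append("")
    if "statehmm" in st and st["statehmm"].get("per_severity"):
        lines.append("## Hidden-state journey models")
        for sev, info in st["statehmm"]["per_severity"].items():
            if info.get("skipped"):
                lines.append(f"- {sev}: skipped ({info.get('n_users', 0)} users)")
                continue
            sel = info.get("selection")
            if sel:
                curve = ", ".join(f"K={k}: {e:.3f}" for k, e in sel["error_curve"])
                lines.append(
                    f"- {sev} ({info['n_users']} users): best K = {sel['best_K']} ({curve})"
                )
            else:
                lines.append(f"- {sev} ({info['n_users']} users): K = {info['K']}")
        lines.append("")
    if "social" in st and st["social"].get("n_pairs"):
        s = st["social"]
        lines += ["## Co-search pairs", f"- pairs: {s['n_pairs']}"]
        if "enrichment" in s and s["enrichment"].get("fold_defined"):
            e = s["enrichment"]
            lines.append(
                f"- fold enrichment: {e['fold_enrichment']:.2f} (p={e['p_value']:.4g})"
            )
        if "overlap" in s:
            o = s["overlap"]
            lines.append(
                f"- disease overlap: {o['observed_overlap']:.2f} vs random {o['random_match_baseline']:.2f}"
            )
        lines.append("")
    if "regress" in st and "r2" in st.get("regress", {}):
        r = st["regress"]
        lines += ["## Incidence regression", f"- R²: {r['r2']:.3f}", ""]
    (out / "report.md").write_text("\n".join(lines), encoding="utf-8")
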