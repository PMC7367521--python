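"""End-to-end orchestration: simulate -> screen -> design -> sample ->
code -> estimate / agree / assoc, with a reproducible manifest.

A single global seed is fanned out to per-stage streams through fixed
integer labels, so each stage is independently reproducible and the
manifest alone suffices to re-run the pipeline identically. Reports are
CSV/JSON-lines; the manifest records the seed, stage counts (the
collection -> screening -> sampling -> analysis funnel) and file names.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
import pathlib
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agree import assess_agreement
from .assoc import or_table
from .coding import Phrasebook, code_sample, reconcile_matrix
from .constants import DRUGS, RISKS, mention_col
from .design import DesignParams, StratifiedSampler, allocate, build_strata, sample_size, strata_frame
from .estimate import origin_share, quarterly_series, sample_percentage, table2_shape, weighted_total
from .posts import read_jsonl, write_jsonl
from .screen import DomainRegistry, ExclusionRules, Lexicon, funnel_counts, screen_corpus
from .synth import CorpusConfig, SurgeSpec, default_config, generate_corpus, simulate_raters

logger = logging.getLogger(__name__)

_STAGE_SEED_LABELS = {"simulate": 11, "sample": 13, "raters": 17}


def _stage_seed(seed: int, stage: str, extra: int = 0) -> int:
    return (seed * 1_000_003 + _STAGE_SEED_LABELS[stage] * 7919 + extra) % (2**31)


@dataclasses.dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    outdir: pathlib.Path
    seed: int = 0
    corpus_path: Optional[pathlib.Path] = None
    corpus_config: Optional[CorpusConfig] = None
    design: DesignParams = dataclasses.field(default_factory=DesignParams)
    n_total: Optional[int] = None  # overrides the solver when set
    rater_error_rates: tuple = (0.02, 0.02, 0.02)
    apply_rules: bool = True
    run_agree: bool = True
    run_assoc: bool = True

    @classmethod
    def from_yaml(cls, path, outdir=None) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        corpus_config = None
        if "simulate" in raw:
            corpus_config = _corpus_config_from_dict(raw["simulate"], raw.get("seed", 0))
        design = DesignParams(**raw.get("design", {}))
        return cls(
            outdir=pathlib.Path(outdir or raw.get("outdir", "run")),
            seed=int(raw.get("seed", 0)),
            corpus_path=pathlib.Path(raw["corpus"]) if raw.get("corpus") else None,
            corpus_config=corpus_config,
            design=design,
            n_total=raw.get("n_total"),
            rater_error_rates=tuple(raw.get("rater_error_rates", (0.02, 0.02, 0.02))),
            apply_rules=bool(raw.get("apply_rules", True)),
            run_agree=bool(raw.get("run_agree", True)),
            run_assoc=bool(raw.get("run_assoc", True)),
        )


def _corpus_config_from_dict(raw: dict, seed: int) -> CorpusConfig:
    base = default_config(seed=seed)
    surge = base.surge
    if "surge" in raw:
        s = raw["surge"]
        surge = (
            None
            if s is None
            else SurgeSpec(s["drug"], datetime.date.fromisoformat(str(s["onset"])), float(s["multiplier"]))
        )
    return CorpusConfig(
        start_date=datetime.date.fromisoformat(str(raw.get("start_date", base.start_date))),
        end_date=datetime.date.fromisoformat(str(raw.get("end_date", base.end_date))),
        weekly_volume=raw.get("weekly_volume", base.weekly_volume),
        prevalence=raw.get("prevalence", base.prevalence),
        origin_effect=raw.get("origin_effect", base.origin_effect),
        surge=surge,
        spam_fraction=float(raw.get("spam_fraction", base.spam_fraction)),
        misspelling_prob=float(raw.get("misspelling_prob", base.misspelling_prob)),
        reply_fraction=float(raw.get("reply_fraction", base.reply_fraction)),
        secondary_mention_prob=float(raw.get("secondary_mention_prob", base.secondary_mention_prob)),
        non_english_fraction=float(raw.get("non_english_fraction", base.non_english_fraction)),
        non_us_fraction=float(raw.get("non_us_fraction", base.non_us_fraction)),
        seed=seed,
    )


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""


def _log_stage(name: str, **fields):
    logger.info(json.dumps({"stage": name, **fields}, sort_keys=True))


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    out = pathlib.Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "stages": {},
        "files": {},
    }
    phrasebook = Phrasebook.load_default()
    lexicon = Lexicon.load_default()
    registry = DomainRegistry.load_default()
    rules = ExclusionRules.load_default()

    stage = "simulate"
    try:
        if config.corpus_path is not None:
            corpus = read_jsonl(config.corpus_path)
            window = (
                pd.to_datetime(corpus["timestamp"]).min().date(),
                pd.to_datetime(corpus["timestamp"]).max().date(),
            )
        else:
            corpus_config = config.corpus_config or default_config(
                seed=_stage_seed(config.seed, "simulate")
            )
            corpus, truth = generate_corpus(corpus_config, phrasebook)
            window = (corpus_config.start_date, corpus_config.end_date)
            write_jsonl(corpus, out / "corpus.jsonl")
            write_jsonl(truth.posts, out / "truth.jsonl")
            manifest["files"]["corpus"] = "corpus.jsonl"
            manifest["files"]["truth"] = "truth.jsonl"
        manifest["stages"]["collected"] = int(len(corpus))
        _log_stage(stage, collected=len(corpus))
    except Exception as exc:
        raise StageError(f"stage {stage}: {exc}") from exc

    stage = "screen"
    try:
        if config.apply_rules:
            screened = screen_corpus(corpus, lexicon, rules, registry, window)
        else:
            screened = screen_corpus(
                corpus,
                lexicon,
                ExclusionRules(order=[], allowed_languages=["en"], allowed_countries=["US"], phrases={}),
                registry,
                window,
            )
        write_jsonl(screened, out / "screened.jsonl")
        manifest["files"]["screened"] = "screened.jsonl"
        funnel = funnel_counts(screened)
        manifest["stages"]["screened_retained"] = funnel["retained"]
        manifest["stages"]["excluded_by_reason"] = funnel["excluded"]
        _log_stage(stage, **{"retained": funnel["retained"]})
    except Exception as exc:
        raise StageError(f"stage {stage}: {exc}") from exc

    stage = "design"
    try:
        all_strata = {}
        design_frames = []
        for drug in DRUGS:
            strata = build_strata(screened, drug, window)
            if not strata:
                continue
            total_N = sum(s.N_h for s in strata)
            n_drug = config.n_total if config.n_total is not None else sample_size(total_N, config.design)
            n_drug = min(max(n_drug, len(strata)), total_N)
            strata = allocate(strata, n_drug)
            all_strata[drug] = strata
            design_frames.append(strata_frame(strata))
        design_df = pd.concat(design_frames, ignore_index=True) if design_frames else pd.DataFrame()
        design_df.to_csv(out / "design.csv", index=False)
        manifest["files"]["design"] = "design.csv"
        manifest["stages"]["strata"] = int(len(design_df))
        _log_stage(stage, strata=len(design_df))
    except Exception as exc:
        raise StageError(f"stage {stage}: {exc}") from exc

    stage = "code"
    try:
        coded_by_drug = {}
        for di, (drug, strata) in enumerate(all_strata.items()):
            sampler = StratifiedSampler(strata, screened)
            sampled = sampler.draw(_stage_seed(config.seed, "sample", di))
            coded_by_drug[drug] = code_sample(sampled, phrasebook)
        sampled_total = sum(len(c) for c in coded_by_drug.values())
        manifest["stages"]["sampled"] = int(sampled_total)
        coded_all = (
            pd.concat(coded_by_drug.values(), ignore_index=True)
            if coded_by_drug
            else pd.DataFrame()
        )
        keep_cols = [
            "post_id",
            "sample_drug",
            "stratum",
            "weight",
            "origin_class",
            "misuse_abuse",
            "misuse",
            "abuse",
            "addiction",
            "overdose",
            "death",
        ] + [mention_col(d) for d in DRUGS if coded_all.columns.isin([mention_col(d)]).any()]
        coded_all[keep_cols].to_csv(out / "coded_sample.csv", index=False)
        manifest["files"]["coded_sample"] = "coded_sample.csv"
        _log_stage(stage, sampled=sampled_total)
    except Exception as exc:
        raise StageError(f"stage {stage}: {exc}") from exc

    stage = "agree"
    final_by_drug = coded_by_drug
    agreement_df = None
    if config.run_agree and coded_by_drug:
        try:
            matrices = {}
            final_by_drug = {}
            for di, (drug, coded) in enumerate(coded_by_drug.items()):
                final = coded.copy()
                for vi, variable in enumerate(("misuse_abuse", "addiction", "overdose", "death")):
                    labels = (
                        (coded["misuse_abuse"] != "none").to_numpy()
                        if variable == "misuse_abuse"
                        else coded[variable].to_numpy()
                    )
                    matrix = simulate_raters(
                        labels,
                        config.rater_error_rates,
                        seed=_stage_seed(config.seed, "raters", di * 10 + vi),
                    )
                    key = variable
                    if key in matrices:
                        matrices[key] = np.vstack([matrices[key], matrix])
                    else:
                        matrices[key] = matrix
                    reconciled = reconcile_matrix(matrix, labels.astype(int)).astype(bool)
                    if variable == "misuse_abuse":
                        # final subtype: keep the machine-coded subtype where it
                        # exists, defaulting to misuse for rater-introduced positives
                        subtype = coded["misuse_abuse"].where(
                            coded["misuse_abuse"] != "none", "misuse"
                        )
                        final["misuse_abuse"] = np.where(reconciled, subtype, "none")
                        final["misuse"] = final["misuse_abuse"] == "misuse"
                        final["abuse"] = final["misuse_abuse"] == "abuse"
                    else:
                        final[variable] = reconciled
                final_by_drug[drug] = final
            agreement_df = assess_agreement(matrices)
            agreement_df.to_csv(out / "agreement.csv", index=False)
            manifest["files"]["agreement"] = "agreement.csv"
            _log_stage(stage, variables=len(matrices))
        except Exception as exc:
            raise StageError(f"stage {stage}: {exc}") from exc

    stage = "estimate"
    try:
        tidy_rows = []
        quarterly_frames = []
        share_rows = []
        analyzed = 0
        for drug, coded in final_by_drug.items():
            strata = all_strata[drug]
            analyzed += len(coded)
            for risk in RISKS:
                est = weighted_total(coded, risk, strata, label=f"{drug}:{risk}")
                tidy_rows.append(
                    {
                        "drug": drug,
                        "risk": risk,
                        "k_sample": int(coded[risk].sum()),
                        "n_sample": est.n_sample,
                        "pct_sample": sample_percentage(int(coded[risk].sum()), len(coded)),
                        "point": est.point,
                        "se": est.se,
                        "ci_lo": est.ci_lo,
                        "ci_hi": est.ci_hi,
                    }
                )
                quarterly_frames.append(quarterly_series(coded, strata, drug, risk))
            try:
                share = origin_share(coded, strata, drug)
                share_rows.append(
                    {
                        "drug": drug,
                        "blogs_forums_share": share.point,
                        "se": share.se,
                        "ci_lo": share.ci_lo,
                        "ci_hi": share.ci_hi,
                        "n_keyrisk": share.n_sample,
                    }
                )
            except ValueError as exc:
                logger.warning("origin share skipped for %s: %s", drug, exc)
        estimates = pd.DataFrame(tidy_rows)
        estimates.to_csv(out / "estimates.csv", index=False)
        if not estimates.empty:
            table2_shape(estimates).to_csv(out / "table2.csv")
            manifest["files"]["table2"] = "table2.csv"
        if quarterly_frames:
            pd.concat(quarterly_frames, ignore_index=True).to_csv(
                out / "quarterly_series.csv", index=False
            )
            manifest["files"]["quarterly_series"] = "quarterly_series.csv"
        pd.DataFrame(share_rows).to_csv(out / "origin_share.csv", index=False)
        manifest["files"]["estimates"] = "estimates.csv"
        manifest["files"]["origin_share"] = "origin_share.csv"
        manifest["stages"]["analyzed"] = int(analyzed)
        _log_stage(stage, analyzed=analyzed)
    except Exception as exc:
        raise StageError(f"stage {stage}: {exc}") from exc

    stage = "assoc"
    if config.run_assoc and final_by_drug:
        try:
            ors = or_table(final_by_drug)
            ors.to_csv(out / "odds_ratios.csv", index=False)
            manifest["files"]["odds_ratios"] = "odds_ratios.csv"
            _log_stage(stage, contrasts=len(ors))
        except Exception as exc:
            raise StageError(f"stage {stage}: {exc}") from exc

    with open(out / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return manifest
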