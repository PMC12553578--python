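"""End-to-end orchestration with a single validated configuration.

``run_all`` executes every analysis stage on one occurrence/trait input
pair and collects the stage results into a deterministic, JSON-serializable
report. Stage failures abort with the stage name attached so a partial run
is never silently reported as complete.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import activity, benford, ingest, phylo, representation, trait_model

__all__ = ["RunConfig", "run_all", "StageError"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    occurrences: str = ""
    traits: str = ""
    tree: str | None = None
    out_dir: str = "obsbias_out"
    dialect: dict = field(default_factory=dict)
    domestic_list: str | None = None  # path; None = shipped default
    period_policy: str = "crepuscular_priority"
    glm_reference: str = "cathemeral"
    benford_digits: int = 2
    nsim: int = 1000
    seed: int = 0
    model: dict = field(default_factory=dict)  # ModelSpec field overrides

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.occurrences or not self.traits:
            raise ValueError("config must set both 'occurrences' and 'traits' paths")
        for label, p in (("occurrences", self.occurrences), ("traits", self.traits)):
            if not Path(p).exists():
                raise FileNotFoundError(f"{label} file not found: {p}")
        if self.tree is not None and not Path(self.tree).exists():
            raise FileNotFoundError(f"tree file not found: {self.tree}")
        if self.period_policy not in activity.POLICIES:
            raise ValueError(f"period_policy must be one of {activity.POLICIES}")
        if self.benford_digits not in (1, 2):
            raise ValueError("benford_digits must be 1 or 2")
        if self.nsim < 1:
            raise ValueError("nsim must be positive")
        bad = set(self.model) - set(trait_model.ModelSpec.__dataclass_fields__)
        if bad:
            raise ValueError(f"unknown model spec keys: {sorted(bad)}")


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc

        return wrapped

    return deco


@_stage("ingest")
def _run_ingest(cfg: RunConfig):
    domestic = None
    if cfg.domestic_list:
        with open(cfg.domestic_list) as fh:
            domestic = frozenset(
                line.strip() for line in fh if line.strip() and not line.startswith("#")
            )
    return ingest.ingest(cfg.occurrences, cfg.traits, cfg.dialect or None, domestic)


def run_all(cfg: RunConfig) -> dict:
    """Run every stage and return (and persist) the consolidated report."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    records, profiles, report = _run_ingest(cfg)
    frame = ingest.profiles_to_frame(profiles)
    frame.to_csv(out / "species_profiles.csv", index=False)

    bundle: dict = {"seed": cfg.seed, "ingest": json.loads(report.to_json())}
    bundle["realm_totals"] = ingest.count_by_realm(profiles)

    @_stage("benford")
    def _benford():
        counts = frame["n_obs"].to_numpy()
        return benford.benford_test(counts, cfg.benford_digits).to_dict()

    bundle["benford"] = _benford()

    @_stage("representation")
    def _represent():
        by_order = frame[frame["order_name"] != ""].groupby("order_name").agg(
            richness=("species", "size"), observed=("n_obs", "sum")
        )
        reps = representation.expected_by_richness(
            {o: (int(r.richness), int(r.observed)) for o, r in by_order.iterrows()}
        )
        chi2, df, p = representation.gof_chi_square(reps)
        rank = representation.spearman_rank(by_order["richness"], by_order["observed"])
        rows = [vars(r) for r in reps]
        marine = representation.group_mean_obs(
            profiles, lambda p_: "marine" if "marine" in p_.strata else "terrestrial"
        )
        return {
            "orders": rows,
            "n_over": sum(r.status == "over" for r in reps),
            "n_under": sum(r.status == "under" for r in reps),
            "gof_chi2": chi2,
            "gof_df": df,
            "gof_p": p,
            "spearman": vars(rank),
            "group_mean_obs": marine,
        }

    bundle["representation"] = _represent()

    @_stage("alignment")
    def _align():
        pattern_by_species = {
            p.species: activity.derive_pattern(p.diurnal, p.nocturnal, p.crepuscular)
            for p in profiles
            if None not in (p.diurnal, p.nocturnal, p.crepuscular)
        }
        hours, patterns = [], []
        for rec in records:
            pat = pattern_by_species.get(rec.scientific_name)
            if pat is None:
                continue
            hours.append(np.nan if rec.hour is None else rec.hour)
            patterns.append(pat)
        summary = activity.alignment_summary(
            hours, patterns, policy=cfg.period_policy, reference=cfg.glm_reference
        )
        return summary.to_dict()

    bundle["alignment"] = _align()

    @_stage("welch")
    def _welch():
        sub = frame.dropna(subset=["diurnal", "body_mass_g"])
        diurnal = sub[sub["diurnal"] == 1]["body_mass_g"]
        other = sub[sub["diurnal"] != 1]["body_mass_g"]
        if len(diurnal) < 2 or len(other) < 2:
            return None
        return vars(phylo.welch_t(diurnal, other))

    bundle["welch_body_mass"] = _welch()

    if cfg.tree is not None:

        @_stage("phylanova")
        def _phyl():
            tree = phylo.read_newick(cfg.tree)
            tips = set(phylo.tip_labels(tree))
            sub = frame.dropna(subset=["diurnal", "body_mass_g"])
            sub = sub[sub["species"].isin(tips)]
            keep = set(sub["species"])
            dropped = sorted(tips - keep)
            if dropped:
                tree.retain_taxa_with_labels(sorted(keep))
            if tree.length() == 0:
                tree = phylo.grafen_brlen(tree)
            values = dict(zip(sub["species"], np.log(sub["body_mass_g"])))
            groups = dict(zip(sub["species"], sub["diurnal"].astype(int)))
            res = phylo.phyl_anova(tree, values, groups, nsim=cfg.nsim, seed=cfg.seed)
            return vars(res) | {"n_tips_dropped": len(dropped)}

        bundle["phylanova"] = _phyl()

    @_stage("trait_model")
    def _model():
        spec = trait_model.ModelSpec(**cfg.model)
        mframe = trait_model.prepare_model_frame(frame, spec)
        res = trait_model.fit_lmm(mframe, spec)
        res.coefficients.to_csv(out / "model_coefficients.csv")
        return res.to_dict()

    bundle["trait_model"] = _model()

    with open(out / "report.json", "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True, default=float)
    return bundle
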