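"""End-to-end orchestration of the comorbidity network analysis.

A single configuration drives the whole pipeline: load (or synthesize) a
questionnaire panel, apply the response-time filters and nomophobia
inclusion rule where the relevant columns exist, binarize, estimate three
Ising networks (depression-only, anxiety-only, combined), compute
centralities (bridge EI only for the combined network, where the two
a-priori communities meet), run bootstrap accuracy/stability diagnostics,
simulate alleviating and aggravating interventions, fit the
continuous-score partial-correlation networks, and compare binary vs
continuous structure with Mantel tests.  All randomness derives from one
seed, so a rerun with the same configuration reproduces every artifact
byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .centrality import centrality_table
from .ggm_compare import estimate_ggm, mantel_test
from .ising_fit import fit_ising
from .models import BinaryMatrix, SymptomPanel
from .nira import run_nira_both
from .preprocessing import binarize, describe, filter_by_response_time
from .stability import case_dropping, cs_coefficient, nonparametric_bootstrap
from .synthetic_data import default_panel_spec, generate_ordinal_panel

__all__ = ["PipelineConfig", "run_pipeline", "export_tables"]

log = logging.getLogger(__name__)

NETWORKS = ("depression", "anxiety", "comorbidity")


@dataclass
class PipelineConfig:
    """Settings for a full pipeline run.

    Defaults follow the study conventions for this analysis: eLasso EBIC
    gamma 0.25, 1,000 bootstrap resamples, 5,000 Metropolis-Hastings
    samples per intervention condition with perturbation magnitude 2 SD,
    and seed 123.
    """

    input_csv: str | None = None          # participants x items CSV
    synthetic_n: int = 1638               # used when input_csv is None
    gamma: float = 0.25
    n_lambda: int = 100
    bootstrap_B: int = 1000
    casedrop_B: int = 1000
    casedrop_proportions: tuple[float, ...] = (0.1, 0.2, 0.25, 0.3, 0.4, 0.5, 0.6, 0.7, 0.75)
    nira_iterations: int = 5000
    nira_magnitude: float = 2.0
    seed: int = 123
    mantel_permutations: int = 999
    ggm_gamma: float = 0.5
    output_dir: str = "symptomnet_output"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "casedrop_proportions" in raw:
            raw["casedrop_proportions"] = tuple(raw["casedrop_proportions"])
        defaults = cls()
        for key, value in raw.items():
            if value != getattr(defaults, key):
                log.info("config override: %s = %r", key, value)
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["casedrop_proportions"] = list(self.casedrop_proportions)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _load_or_synthesize(config: PipelineConfig) -> SymptomPanel:
    from .preprocessing import load_panel

    if config.input_csv:
        return load_panel(config.input_csv)
    spec = default_panel_spec(n=config.synthetic_n, seed=config.seed)
    return generate_ordinal_panel(spec)


def _child_seed(base: int, tag: str) -> int:
    h = hashlib.sha256(f"{base}:{tag}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage and return the result bundle.

    The bundle maps stage names to in-memory results; ``export_tables``
    writes it to disk.  Bridge EI appears only in the combined network,
    where the depression and anxiety communities are both present.
    """
    panel = _load_or_synthesize(config)

    filter_info = None
    if panel.response_times is not None:
        res = filter_by_response_time(panel.response_times)
        keep = res.kept
        panel = SymptomPanel(
            scores=panel.scores.iloc[keep].reset_index(drop=True),
            item_scales=panel.item_scales,
            score_ranges=panel.score_ranges,
            response_times=panel.response_times.iloc[keep].reset_index(drop=True),
        )
        filter_info = {
            "n_fast": int(len(res.fast)),
            "n_slow": int(len(res.slow)),
            "slow_cutoff_s": res.slow_cutoff,
            "n_kept": int(len(res.kept)),
        }
        log.info("response-time filter kept %d participants", len(keep))

    summary = describe(panel)
    binary = binarize(panel)
    comm = panel.communities()
    groups = {
        "depression": [n for n, c in comm.items() if c == "depression"],
        "anxiety": [n for n, c in comm.items() if c == "anxiety"],
    }
    if not groups["depression"] or not groups["anxiety"]:
        raise ValueError(
            "input must contain both PHQ (depression) and GAD (anxiety) items; "
            f"found communities: { {k: len(v) for k, v in groups.items()} }"
        )

    nets: dict[str, dict[str, Any]] = {}
    for name in NETWORKS:
        sub = binary if name == "comorbidity" else binary.subset(groups[name])
        model = fit_ising(sub, gamma=config.gamma, n_lambda=config.n_lambda)
        cent = centrality_table(model)
        boot = nonparametric_bootstrap(
            sub, B=config.bootstrap_B, seed=_child_seed(config.seed, f"boot:{name}"),
            gamma=config.gamma, n_lambda=config.n_lambda,
        )
        curve = case_dropping(
            sub, proportions=config.casedrop_proportions, B=config.casedrop_B,
            seed=_child_seed(config.seed, f"drop:{name}"),
            gamma=config.gamma, n_lambda=config.n_lambda,
        )
        nira = run_nira_both(
            model, iterations=config.nira_iterations,
            magnitude=config.nira_magnitude,
            seed=_child_seed(config.seed, f"nira:{name}"),
        )
        ggm = estimate_ggm(panel, gamma=config.ggm_gamma, items=sub.nodes)
        mantel = mantel_test(
            ggm.partials, model.omega, n_perm=config.mantel_permutations,
            seed=_child_seed(config.seed, f"mantel:{name}"),
        )
        nets[name] = {
            "model": model,
            "centrality": cent,
            "bootstrap": boot,
            "stability_curve": curve,
            "cs_coefficient": cs_coefficient(curve),
            "nira": nira,
            "ggm": ggm,
            "mantel": mantel,
        }
        log.info(
            "%s network: %d edges, CS-C(EI)=%.2f, Mantel r=%.3f (p=%.3g)",
            name, model.n_edges, nets[name]["cs_coefficient"], mantel.r, mantel.p,
        )

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "n_participants": panel.n,
        "filter": filter_info,
    }
    return {"panel": panel, "summary": summary, "networks": nets, "manifest": manifest}


def export_tables(bundle: dict[str, Any], outdir: str | Path) -> list[Path]:
    """Write the bundle as CSV/JSON artifacts; returns the file list.

    Layout: cohort descriptives and group breakdown at the top level; per
    network, the model JSON, edge list, centrality table, bootstrapped
    edge CIs, stability curve (long format), CS coefficient, the ranked
    intervention tables (sorted by outcome, descending), the GGM, and the
    Mantel result.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if bundle["panel"].n == 0:
        raise ValueError("empty cohort; nothing to export")
    written: list[Path] = []

    def save_csv(df: pd.DataFrame, rel: str, index: bool = False) -> None:
        path = out / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, index=index, float_format="%.10g")
        written.append(path)

    def save_json(obj: Any, rel: str) -> None:
        path = out / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(obj, indent=2, sort_keys=True))
        written.append(path)

    summary = bundle["summary"]
    save_csv(summary.items.reset_index(), "cohort_descriptives.csv")
    save_json(summary.to_json_dict(), "cohort_groups.json")

    for name, res in bundle["networks"].items():
        base = f"network_{name}"
        save_json(res["model"].to_dict(), f"{base}/model.json")
        save_csv(res["model"].edge_list(), f"{base}/edges.csv")
        save_csv(res["centrality"].reset_index(), f"{base}/centrality.csv")
        save_csv(res["bootstrap"].summary(), f"{base}/edge_bootstrap.csv")
        save_csv(res["stability_curve"].samples, f"{base}/stability_curve.csv")
        save_json(
            {
                "cs_coefficient": res["cs_coefficient"],
                "centrality": res["stability_curve"].centrality,
                "interpretation_bands": {"acceptable": 0.25, "good": 0.5, "excellent": 0.75},
            },
            f"{base}/cs_coefficient.json",
        )
        for direction, nira in res["nira"].items():
            save_csv(nira.table, f"{base}/nira_{direction}.csv")
            save_json(
                {"baseline": nira.baseline, "settings": nira.settings},
                f"{base}/nira_{direction}_baseline.json",
            )
        save_json(res["ggm"].to_dict(), f"{base}/ggm.json")
        save_json(res["mantel"].to_dict(), f"{base}/mantel.json")

    save_json(bundle["manifest"], "manifest.json")
    return written
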