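"""End-to-end orchestration: load, constrain, solve, classify, screen, report.

:func:`run_snf_analysis` is the library equivalent of a batch driver: given
a :class:`RunConfig` it loads (or generates) a model, applies the SNF
objective and symbiotic medium when asked to, and writes six deterministic
reports to the output directory:

* ``model_summary.tsv`` — reconstruction headline counts
* ``fluxes.tsv``        — optimal flux distribution
* ``pathway_activity.tsv`` — active/inactive call per subsystem
* ``essentiality.tsv``  — per-gene deletion outcomes + aggregate line
* ``gaps.tsv``          — dead-end metabolites and blocked reactions
* ``manifest.json``     — config echo, package version, report checksums

Reports are byte-identical across reruns with the same config and inputs;
anything time-dependent is excluded.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass
from typing import Dict, Optional

import pandas as pd

from . import __version__
from .essentiality import (DEFAULT_THRESHOLD_FRACTION, screen_essential_genes)
from .fba import DEFAULT_EPSILON, classify_pathway_activity, solve_fba
from .gaps import gap_report
from .model import Model, ReactionKind, assert_valid, summarize_model
from .sbml import read_sbml
from .snf import MediumSpec, apply_symbiotic_medium, load_medium


class AnalysisInfeasibleError(RuntimeError):
    """Wild-type model cannot reach a positive objective; carries diagnostics."""

    def __init__(self, message: str, diagnostics: Dict[str, list]):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass
class RunConfig:
    model_path: Optional[str] = None  # SBML; None -> caller passes a Model
    medium_path: Optional[str] = None  # YAML; None -> bounds left as loaded
    output_dir: str = "snf_run"
    epsilon: float = DEFAULT_EPSILON
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epsilon <= 0 or self.threshold_fraction <= 0:
            raise ValueError("epsilon and threshold_fraction must be > 0")


def _diagnose_infeasibility(model: Model) -> Dict[str, list]:
    from .gaps import find_dead_end_metabolites
    closed = sorted(
        r.id for r in model.exchanges()
        if r.lower_bound >= 0 and r.upper_bound <= 0)
    closed_uptake = sorted(
        r.id for r in model.exchanges() if r.lower_bound >= 0)
    dead = find_dead_end_metabolites(model).dead_end_metabolites
    return {
        "closed_exchanges": closed,
        "uptake_closed_exchanges": closed_uptake,
        "dead_end_metabolites": [(d.metabolite_id, d.kind) for d in dead],
    }


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()


def run_snf_analysis(config: RunConfig, model: Optional[Model] = None,
                     medium: Optional[MediumSpec] = None) -> str:
    """Run the full analysis; returns the report directory path.

    The model comes from ``config.model_path`` (SBML) or the ``model``
    argument; likewise the medium. Raises
    :class:`AnalysisInfeasibleError` with exchange/dead-end diagnostics if
    the wild type cannot fix nitrogen.
    """
    if model is None:
        if config.model_path is None:
            raise ValueError("RunConfig.model_path or a Model is required")
        model = read_sbml(config.model_path)
    assert_valid(model)
    if medium is None and config.medium_path is not None:
        medium = load_medium(config.medium_path)
    if medium is not None:
        apply_symbiotic_medium(model, medium)

    wt = solve_fba(model)
    if not wt.optimal or wt.objective_value <= 0:
        raise AnalysisInfeasibleError(
            f"wild-type FBA is {wt.status} with objective "
            f"{wt.objective_value!r}; the bacteroid cannot fix nitrogen "
            "under these constraints", _diagnose_infeasibility(model))

    out = config.output_dir
    os.makedirs(out, exist_ok=True)

    summary = summarize_model(model)
    pd.DataFrame([summary.as_dict()]).T.reset_index() \
        .set_axis(["quantity", "count"], axis=1) \
        .to_csv(os.path.join(out, "model_summary.tsv"), sep="\t", index=False)

    flux_rows = sorted(wt.fluxes.items())
    pd.DataFrame(flux_rows, columns=["reaction", "flux"]).to_csv(
        os.path.join(out, "fluxes.tsv"), sep="\t", index=False)

    activity = classify_pathway_activity(model, epsilon=config.epsilon)
    pd.DataFrame(
        [(a.subsystem, a.status, a.evidence) for a in activity],
        columns=["subsystem", "status", "max_abs_flux"]).to_csv(
        os.path.join(out, "pathway_activity.tsv"), sep="\t", index=False)

    screen = screen_essential_genes(
        model, threshold_fraction=config.threshold_fraction)
    frame = screen.to_frame()
    frame.to_csv(os.path.join(out, "essentiality.tsv"), sep="\t", index=False)
    with open(os.path.join(out, "essentiality_summary.tsv"), "w") as fh:
        fh.write("n_genes_screened\tn_essential\tfraction_essential\n")
        fh.write(f"{screen.n_genes_screened}\t{screen.n_essential}\t"
                 f"{screen.fraction_essential:.6f}\n")

    gaps = gap_report(model)
    with open(os.path.join(out, "gaps.tsv"), "w") as fh:
        fh.write("kind\tentity\tdetail\n")
        for d in gaps.dead_end_metabolites:
            fh.write(f"dead_end\t{d.metabolite_id}\t{d.kind}\n")
        for rid in gaps.blocked_reactions:
            fh.write(f"blocked_reaction\t{rid}\t\n")

    reports = ["model_summary.tsv", "fluxes.tsv", "pathway_activity.tsv",
               "essentiality.tsv", "essentiality_summary.tsv", "gaps.tsv"]
    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "wildtype_objective": wt.objective_value,
        "checksums": {name: _sha256(os.path.join(out, name))
                      for name in reports},
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
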