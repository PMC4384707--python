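"""Synthetic biodistribution, expression, and annotation generator.

Emulates the statistical structure the analysis stages assume, with a
recorded ground truth, so the full pipeline is testable without any
external data:

* per-organ time-activity curves from a two-rate uptake/clearance model
  with physical decay,
* a probes x samples log2 expression matrix over the exposure grid
  {control, (1.7 kBq, 1 h), (1.7 kBq, 6 h), (1.7 kBq, 7 d),
  (105 kBq, 1 h), (7.5 kBq, 6 h)} with 3 (reference) / 2 (elevated)
  biological replicates, technical triplicates, planted fold changes
  and Gaussian log-scale noise,
* a transcript -> GO-term annotation with planted over-represented terms
  and a term -> (category, subcategory) map.

All randomness flows from the single design seed through named
generators; identical designs produce identical outputs.
"""

from __future__ import annotations

import importlib.resources
import json
import math
import zlib
from dataclasses import asdict, dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from atdose.dosimetry import AT211_HALF_LIFE_H, TimeActivityCurve
from atdose.diffexpr import ExpressionStudy
from atdose.profiles import AnnotationMap
from atdose.screen import ExposureGrid


@dataclass(frozen=True)
class OrganKinetics:
    """Uptake/clearance parameters of one organ.

    ``uptake_fraction`` is the fraction of injected activity taken up at
    peak; ``k_uptake``/``k_clear`` are first-order rates in 1/h
    (``k_uptake = inf`` means instantaneous uptake); mass in kg.
    """

    uptake_fraction: float
    k_uptake_per_h: float
    k_clear_per_h: float
    mass_kg: float

    def __post_init__(self) -> None:
        if self.uptake_fraction < 0:
            raise ValueError("uptake fraction cannot be negative")
        if self.k_uptake_per_h < 0 or self.k_clear_per_h < 0:
            raise ValueError("rates cannot be negative")
        if self.mass_kg <= 0:
            raise ValueError("mass must be positive")


DEFAULT_ORGANS: dict[str, OrganKinetics] = {
    "kidney_cortex": OrganKinetics(0.010, 10.0, 0.050, 1.5e-4),
    "kidney_medulla": OrganKinetics(0.004, 10.0, 0.060, 0.5e-4),
    "liver": OrganKinetics(0.050, 8.0, 0.030, 1.2e-3),
    "lungs": OrganKinetics(0.030, 12.0, 0.040, 1.5e-4),
    "spleen": OrganKinetics(0.010, 8.0, 0.035, 1.0e-4),
}

#: Biomarker trajectories by pattern: |FC| at (ref 1h, elev 1h, ref 6h,
#: elev 6h, ref 7d).  Gaps are wide relative to FC estimation jitter so
#: planted labels are recoverable; the 7-day fold changes are the
#: smallest, as late responses usually are.
_PATTERN_ABS_FC = {
    "direct": (4.0, 16.0, 4.0, 16.0, 3.0),
    "inverse": (16.0, 4.0, 16.0, 4.0, 3.0),
    "mixed": (4.0, 16.0, 16.0, 4.0, 3.0),
}


@dataclass
class SimulationDesign:
    """Every knob of the synthetic study, with defaults mirroring a
    low-activity in-vivo exposure design (5 tissues; 6 groups; n=3
    reference / n=2 elevated biological replicates; technical
    triplicates; 5,000 probes)."""

    seed: int = 211
    organs: dict[str, OrganKinetics] = field(default_factory=lambda: dict(DEFAULT_ORGANS))
    injected_activity_bq: float = 1700.0
    half_life_h: float = AT211_HALF_LIFE_H
    curve_t_max_h: float = 24.0
    curve_n_samples: int = 49
    curve_decay_corrected: bool = False
    grid: ExposureGrid = field(default_factory=ExposureGrid)
    n_probes: int = 5000
    n_up_per_condition: int = 50
    n_down_per_condition: int = 30
    planted_log2fc: float = 2.0  # |FC| = 4 for per-condition planted probes
    n_biomarkers_per_pattern: int = 5
    n_bio_reference: int = 3
    n_bio_elevated: int = 2
    n_controls: int = 3
    n_tech: int = 3
    control_time_h: float = 24.0
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    noise_sd: float = 0.25      # biological, log2 scale
    noise_sd_tech: float = 0.1  # technical, log2 scale
    n_background_terms: int = 60
    n_planted_terms: int = 5
    term_size_range: tuple[int, int] = (15, 40)
    planted_term_size: int = 30
    enrichment_odds: float = 20.0

    def rng(self, stream: str) -> np.random.Generator:
        """Named child generator: deterministic given (seed, stream)."""
        h = np.random.SeedSequence([self.seed, _stable_hash(stream)])
        return np.random.default_rng(h)


@dataclass
class GroundTruth:
    """What was planted: per-probe truth, pattern labels, enriched terms."""

    probe_truth: pd.DataFrame           # probe, gene, role, log2fc_<cond> columns
    pattern_by_gene: dict[str, str]
    enriched_terms: list[dict]          # term, subcategory, expected high overlap

    def planted_probes(self, condition) -> tuple[set, set]:
        """(up, down) probe sets with a nonzero planted effect at condition."""
        col = _cond_col(condition)
        up = set(self.probe_truth.loc[self.probe_truth[col] > 0, "probe"])
        down = set(self.probe_truth.loc[self.probe_truth[col] < 0, "probe"])
        return up, down

    def to_json(self, path) -> None:
        payload = {
            "probe_truth": self.probe_truth.to_dict(orient="list"),
            "pattern_by_gene": self.pattern_by_gene,
            "enriched_terms": self.enriched_terms,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _cond_col(condition) -> str:
    a, t = condition
    return f"log2fc_{a:g}kbq_{t:g}h"


def _stable_hash(*parts) -> int:
    # reproducible across processes (unlike hash() on str)
    return zlib.crc32("|".join(str(p) for p in parts).encode())


def gen_curves(design: SimulationDesign) -> list[TimeActivityCurve]:
    """Deterministic two-rate uptake/clearance curves per organ.

    ``A(t) = A0 * f * (exp(-k_clear t) - exp(-k_uptake t)) * exp(-lambda t)``
    (physical activity); with ``k_uptake = inf`` the bracket collapses to
    pure clearance, and the degenerate ``k_uptake == k_clear`` case uses
    the ``k t exp(-k t)`` limit form.  When the design asks for
    decay-corrected curves the physical-decay factor is omitted and the
    flag set accordingly.
    """
    t = np.linspace(0.0, design.curve_t_max_h, design.curve_n_samples)
    lam = math.log(2.0) / design.half_life_h
    out = []
    for organ, kin in design.organs.items():
        ku, kc = kin.k_uptake_per_h, kin.k_clear_per_h
        if math.isinf(ku):
            bracket = np.exp(-kc * t)
        elif ku == kc:
            bracket = ku * t * np.exp(-ku * t)
        else:
            bracket = np.exp(-kc * t) - np.exp(-ku * t)
        a = design.injected_activity_bq * kin.uptake_fraction * bracket
        if not design.curve_decay_corrected:
            a = a * np.exp(-lam * t)
        out.append(
            TimeActivityCurve(
                organ=organ,
                times_h=t,
                activities_bq=np.clip(a, 0.0, None),
                decay_corrected=design.curve_decay_corrected,
            )
        )
    return out


def assign_roles(design: SimulationDesign) -> tuple[pd.DataFrame, dict[str, str]]:
    """Deterministic probe role assignment and true per-condition log2 FCs.

    Probes are laid out as: biomarker probes first (one gene per probe,
    except the first direct-pattern gene which gets a second probe
    variant), then disjoint per-condition planted up/down blocks, then
    nulls.  Returns the truth table and the gene -> pattern map.
    """
    grid = design.grid
    conds = list(grid.conditions)
    cond_cols = [_cond_col(c) for c in conds]
    n_bm_genes = 3 * design.n_biomarkers_per_pattern

    probes, genes, roles = [], [], []
    fc = {col: [] for col in cond_cols}
    pattern_by_gene: dict[str, str] = {}

    # --- biomarker genes: significant at every condition, patterned ---
    ref1, el1 = grid.paired_times[0]
    ref6, el6 = grid.paired_times[1] if len(grid.paired_times) > 1 else grid.paired_times[0]
    late = [c for c in grid.reference_conditions if c not in (ref1, ref6)]
    idx = 0
    for pattern in ("direct", "inverse", "mixed"):
        for j in range(design.n_biomarkers_per_pattern):
            gene = f"bm_{pattern}_{j}"
            sign = 1.0 if j % 3 != 2 else -1.0  # mix up- and downregulated
            pattern_by_gene[gene] = pattern
            a1, b1, a6, b6, a7 = _PATTERN_ABS_FC[pattern]
            traj = {ref1: a1, el1: b1, ref6: a6, el6: b6}
            for c in late:
                traj[c] = a7
            n_variants = 2 if (pattern == "direct" and j == 0) else 1
            for v in range(n_variants):
                probes.append(f"probe_{idx:05d}")
                genes.append(gene)
                roles.append("biomarker")
                for c, col in zip(conds, cond_cols):
                    fc[col].append(sign * math.log2(traj[c]))
                idx += 1

    # --- per-condition planted up/down blocks (disjoint) ---
    for c, col_c in zip(conds, cond_cols):
        for direction, n, s in (
            ("up", design.n_up_per_condition, +1.0),
            ("down", design.n_down_per_condition, -1.0),
        ):
            for _ in range(n):
                probes.append(f"probe_{idx:05d}")
                genes.append(f"gene_{idx:05d}")
                roles.append("de")
                for cc, col in zip(conds, cond_cols):
                    fc[col].append(s * design.planted_log2fc if cc == c else 0.0)
                idx += 1

    if idx > design.n_probes:
        raise ValueError(
            f"design plants {idx} probes but has only {design.n_probes}; "
            "raise n_probes or reduce the planted counts"
        )
    # --- nulls ---
    while idx < design.n_probes:
        probes.append(f"probe_{idx:05d}")
        genes.append(f"gene_{idx:05d}")
        roles.append("null")
        for col in cond_cols:
            fc[col].append(0.0)
        idx += 1

    truth = pd.DataFrame({"probe": probes, "gene": genes, "role": roles, **fc})
    return truth, pattern_by_gene


def gen_expression(design: SimulationDesign) -> tuple[ExpressionStudy, GroundTruth]:
    """Expression matrix + sample sheet + ground truth for the design.

    Per probe: a baseline log2 level; per biological sample: baseline
    + planted log2 FC (treated groups only) + N(0, noise_sd); per
    technical replicate: + N(0, noise_sd_tech).  Probes carrying planted
    effects get baselines from the expressed range (one sd above the
    matrix centre) so detection-floor filtering removes only unexpressed
    null probes, as in a real study where regulated transcripts are by
    definition expressed.
    """
    truth, pattern_by_gene = assign_roles(design)
    rng = design.rng("expression")
    n = design.n_probes
    baseline = rng.normal(design.baseline_mean, design.baseline_sd, n)
    planted = (truth["role"] != "null").to_numpy()
    baseline[planted] = rng.normal(
        design.baseline_mean + design.baseline_sd, design.baseline_sd / 3.0,
        planted.sum(),
    )
    # a strongly downregulated transcript must be well expressed at
    # baseline, or its average over treated samples would fall below the
    # detection floor
    fc_cols = [c for c in truth.columns if c.startswith("log2fc_")]
    min_effect = truth[fc_cols].min(axis=1).to_numpy()
    baseline += np.where(min_effect < 0, -min_effect, 0.0)

    conds = list(design.grid.conditions)
    groups: list[tuple[bool, float, float, int]] = [
        (True, 0.0, design.control_time_h, design.n_controls)
    ]
    for act, t in conds:
        n_bio = (
            design.n_bio_reference
            if (act, t) in design.grid.reference_conditions
            else design.n_bio_elevated
        )
        groups.append((False, act, t, n_bio))

    cols: dict[str, np.ndarray] = {}
    rows = []
    for is_control, act, t, n_bio in groups:
        effect = np.zeros(n)
        if not is_control:
            effect = truth[_cond_col((act, t))].to_numpy()
        for b in range(1, n_bio + 1):
            bio = baseline + effect + rng.normal(0.0, design.noise_sd, n)
            for tech in range(1, design.n_tech + 1):
                sid = (
                    f"ctrl_b{b}_t{tech}"
                    if is_control
                    else f"a{act:g}_h{t:g}_b{b}_t{tech}"
                )
                cols[sid] = bio + rng.normal(0.0, design.noise_sd_tech, n)
                rows.append(
                    {
                        "sample_id": sid,
                        "activity_kbq": act,
                        "time_h": t,
                        "bio_rep": b,
                        "tech_rep": tech,
                        "is_control": is_control,
                    }
                )

    matrix = pd.DataFrame(cols, index=pd.Index(truth["probe"], name="probe"))
    samples = pd.DataFrame(rows)
    probe_gene = pd.Series(truth["gene"].to_numpy(), index=truth["probe"].to_numpy())
    study = ExpressionStudy(matrix=matrix, samples=samples, probe_gene=probe_gene)
    gt = GroundTruth(
        probe_truth=truth,
        pattern_by_gene=pattern_by_gene,
        enriched_terms=[],
    )
    return study, gt


def _category_scheme() -> list[tuple[str, str]]:
    ref = importlib.resources.files("atdose.data").joinpath("category_scheme.tsv")
    df = pd.read_csv(ref, sep="\t")
    return list(df.itertuples(index=False, name=None))


def gen_annotation(
    design: SimulationDesign,
    truth: pd.DataFrame | None = None,
) -> tuple[AnnotationMap, GroundTruth]:
    """Transcript -> GO annotation with planted over-represented terms.

    Planted terms draw their member transcripts with ``enrichment_odds``
    weight on probes carrying a planted effect (for the first grid
    condition), so those terms are over-represented among significant
    transcripts; background terms annotate uniformly.  Every term gets a
    (category, subcategory) assignment from the bundled cellular-function
    scheme; planted terms occupy distinct subcategories.
    """
    if truth is None:
        truth, _ = assign_roles(design)
    rng = design.rng("annotation")
    probes = truth["probe"].to_numpy()
    focal_col = _cond_col(design.grid.conditions[0])
    focal = (truth[focal_col] != 0.0).to_numpy()

    scheme = _category_scheme()
    transcript_terms: dict[str, set[str]] = {p: set() for p in probes}
    term_category: dict[str, tuple[str, str]] = {}
    enriched_records = []

    # planted over-represented terms, one per subcategory
    weights = np.where(focal, design.enrichment_odds, 1.0)
    weights = weights / weights.sum()
    for i in range(design.n_planted_terms):
        term = f"GO:91{i:05d}"
        members = rng.choice(probes, size=design.planted_term_size,
                             replace=False, p=weights)
        for m in members:
            transcript_terms[m].add(term)
        cat, sub = scheme[i % len(scheme)]
        term_category[term] = (cat, sub)
        enriched_records.append(
            {"term": term, "category": cat, "subcategory": sub,
             "n_annotated": int(design.planted_term_size),
             "n_planted_overlap": int(focal[np.isin(probes, members)].sum())}
        )

    # uniform background terms
    lo, hi = design.term_size_range
    for i in range(design.n_background_terms):
        term = f"GO:10{i:05d}"
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(probes, size=size, replace=False)
        for m in members:
            transcript_terms[m].add(term)
        cat, sub = scheme[(design.n_planted_terms + i) % len(scheme)]
        term_category[term] = (cat, sub)

    amap = AnnotationMap(
        transcript_terms={p: t for p, t in transcript_terms.items() if t},
        term_category=term_category,
    )
    gt = GroundTruth(
        probe_truth=truth,
        pattern_by_gene={},
        enriched_terms=enriched_records,
    )
    return amap, gt


def simulate_study(design: SimulationDesign):
    """One-call convenience: curves, expression study, annotation, truth."""
    curves = gen_curves(design)
    study, gt = gen_expression(design)
    amap, gt_ann = gen_annotation(design, gt.probe_truth)
    gt.enriched_terms = gt_ann.enriched_terms
    return curves, study, amap, gt
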