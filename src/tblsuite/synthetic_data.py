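"""Synthetic pan-cancer cohorts with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume, so that every stage of the pipeline can be exercised and checked
against planted truth without any external download:

* per-sample somatic **unbalanced events** (deletions / duplications) on
  a regular probe grid, each contributing two chromosomal breaks whose
  copy-number step is at least 0.2 in magnitude and whose flanking
  segments hold at least 20 probes (i.e. the retained class);
* **artifact breaks** that violate at least one retention filter: either
  a sub-threshold step (< 0.135) or a tiny flanking segment (< 20
  probes) with a large step;
* **germline breaks** at cohort-level sites that also appear in at least
  one sample of the matched normal panel;
* MSI samples with an SNV excess (and a reduced break rate), a
  stage-linked break-rate shift, and planted driver genes whose altered
  samples carry a multiplied break rate;
* a negative-binomial expression model in which a configured fraction of
  genes is differentially expressed between the high- and low-burden
  quartiles;
* proportional-hazards survival times with a configurable true hazard
  ratio for the high-burden group and independent censoring.

Probe positions sit on a regular grid per chromosome, which makes
segment sizes in probes and lengths in bp mutually computable. Break
sites are drawn from slots spaced 40 probes apart, so distinct events
never erode each other's flanking-segment sizes. One global seed drives
named substreams per generator, so e.g. changing the decoy stream cannot
perturb the planted signal.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats

__all__ = [
    "ConfigError",
    "AuditError",
    "SimulationConfig",
    "GroundTruth",
    "Cohort",
    "simulate_copy_number_cohort",
    "simulate_sv_calls",
    "simulate_mutations",
    "simulate_expression",
    "simulate_clinical",
    "simulate_cohort",
    "audit_cohort",
    "write_cohort",
]


class ConfigError(ValueError):
    """Invalid or infeasible simulation configuration."""


class AuditError(RuntimeError):
    """Emitted files are inconsistent with the recorded ground truth."""


# named substreams derived from the one global seed
_STREAMS = {
    "germline": 11,
    "segments": 12,
    "sv_decoys": 13,
    "mutations": 14,
    "expression": 15,
    "clinical": 16,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator (rates per sample unless noted)."""

    seed: int = 0
    cancer_types: tuple[str, ...] = ("SIM",)
    n_samples: int = 120            # per cancer type
    n_normals: int = 10

    # genome layout
    n_chromosomes: int = 5
    probes_per_chromosome: int = 2000
    chromosome_length: int = 100_000_000  # bp
    slot_spacing_probes: int = 40

    # somatic breaks (two per unbalanced event; odd remainders are singletons)
    somatic_break_mean: float = 30.0
    somatic_break_count: int | None = None  # fixed per-sample count override
    bimodal_weight: float = 0.0             # mixture weight of the high-rate mode
    bimodal_high_mean: float = 90.0
    break_step_min: float = 0.2             # support of true steps: [min, inf)
    break_step_scale: float = 0.3           # exponential tail above the minimum

    # artifact breaks (violate a retention filter by construction)
    artifact_break_mean: float = 6.0
    artifact_step_range: tuple[float, float] = (0.02, 0.12)  # < 0.135
    artifact_flank_probes: int = 5                            # < 20

    # germline breaks, shared with the normal panel
    n_germline_sites: int = 8
    germline_sample_prob: float = 0.5

    # mutations
    n_mutation_genes: int = 200
    gene_length: int = 200_000  # bp
    tmb_mean: float = 50.0
    tmb_dispersion: float = 0.5
    silent_fraction: float = 0.25
    msi_fraction: float = 0.12
    msi_tmb_multiplier: float = 10.0
    msi_tbl_multiplier: float = 0.5

    # stage
    stage_probs: tuple[float, float, float, float] = (0.30, 0.30, 0.25, 0.15)
    stage_tbl_shift: float = 0.15  # multiplicative break-rate increment per stage step

    # planted drivers (SNV-type alterations that multiply the break rate)
    driver_genes: tuple[str, ...] = ()
    driver_altered_fraction: float = 0.3
    driver_tbl_multiplier: float = 2.0

    # expression
    n_genes: int = 1000
    expr_base_log_mean: float = math.log(100.0)
    expr_base_log_sd: float = 1.0
    expr_dispersion: float = 0.1
    expr_libsize_log_sd: float = 0.2
    de_fraction: float = 0.2
    de_log2fc_range: tuple[float, float] = (0.5, 2.0)

    # survival (times in days)
    baseline_hazard: float = 1.0 / 1000.0
    true_hr_high: float = 2.0
    censoring_rate: float = 0.3

    # balanced decoys for the SV call set
    sv_decoy_mean: float = 3.0
    sv_decoy_fail_fraction: float = 0.2
    decoy_seed: int | None = None   # defaults to the global seed

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_normals < 0:
            raise ConfigError("sample counts must be positive")
        if not 0.0 <= self.bimodal_weight <= 1.0:
            raise ConfigError("bimodal_weight must lie in [0, 1]")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ConfigError("de_fraction must lie in [0, 1]")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ConfigError("censoring_rate must lie in [0, 1)")
        for name in ("somatic_break_mean", "artifact_break_mean", "tmb_mean",
                     "baseline_hazard", "true_hr_high", "expr_dispersion"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.break_step_min < 0.135:
            raise ConfigError("break_step_min below 0.135 would plant filterable breaks")
        if self.artifact_step_range[1] >= 0.135:
            raise ConfigError("artifact steps must stay below 0.135")
        if self.artifact_flank_probes >= 20:
            raise ConfigError("artifact flank must stay below 20 probes")
        if abs(sum(self.stage_probs) - 1.0) > 1e-9:
            raise ConfigError("stage_probs must sum to 1")

    @property
    def probe_spacing(self) -> int:
        return self.chromosome_length // self.probes_per_chromosome

    @property
    def sample_ids(self) -> list[str]:
        return [f"{ct}_T{i:04d}" for ct in self.cancer_types for i in range(1, self.n_samples + 1)]

    def slots(self) -> list[tuple[str, int]]:
        """Candidate break sites as (chromosome, boundary probe index)."""
        sp = self.slot_spacing_probes
        out = []
        for c in range(1, self.n_chromosomes + 1):
            for b in range(sp, self.probes_per_chromosome - sp + 1, sp):
                out.append((str(c), b))
        if not out:
            raise ConfigError("chromosomes too short to host any break slot")
        return out


@dataclass
class GroundTruth:
    """Planted truth, consistent with the emitted files by construction."""

    samples: pd.DataFrame          # sample_id, cancer_type, stage, msi, n_somatic_breaks, tbl_group
    events: dict[str, list]        # sample -> [(chrom, pos_lo_bp, pos_hi_bp|None, sv_type)]
    somatic_breaks: dict[str, list]   # sample -> [(chrom, boundary bp)]
    artifact_breaks: dict[str, list]
    germline_breaks: dict[str, list]
    germline_sites: list           # [(chrom, boundary bp)] shared with the normal panel
    driver_status: pd.DataFrame    # samples x driver genes, boolean
    gene_truth: pd.DataFrame | None = None   # gene, is_de, log2fc
    true_hr: float | None = None

    def to_json(self, path) -> None:
        obj = {
            "samples": self.samples.to_dict(orient="list"),
            "events": self.events,
            "somatic_breaks": self.somatic_breaks,
            "artifact_breaks": self.artifact_breaks,
            "germline_breaks": self.germline_breaks,
            "germline_sites": self.germline_sites,
            "driver_status": self.driver_status.reset_index().to_dict(orient="list"),
            "gene_truth": None if self.gene_truth is None else self.gene_truth.to_dict(orient="list"),
            "true_hr": self.true_hr,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh, indent=1, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(type(o))


@dataclass
class Cohort:
    config: SimulationConfig
    tumor_seg: pd.DataFrame
    normal_seg: pd.DataFrame
    sv: pd.DataFrame
    mutations: pd.DataFrame
    genes: pd.DataFrame
    counts: pd.DataFrame
    clinical: pd.DataFrame
    truth: GroundTruth


# ---------------------------------------------------------------------------
# copy number


def _draw_break_count(cfg: SimulationConfig, rng: np.random.Generator,
                      rate_multiplier: float) -> int:
    if cfg.somatic_break_count is not None:
        return int(cfg.somatic_break_count)
    mean = cfg.somatic_break_mean
    if cfg.bimodal_weight > 0 and rng.random() < cfg.bimodal_weight:
        mean = cfg.bimodal_high_mean
    return int(rng.poisson(mean * rate_multiplier))


def _step(cfg: SimulationConfig, rng: np.random.Generator) -> float:
    return cfg.break_step_min + rng.exponential(cfg.break_step_scale)


def _segments_from_boundaries(sample: str, cfg: SimulationConfig,
                              boundaries: dict[str, list[tuple[int, float]]]) -> list[dict]:
    """Turn per-chromosome (probe index, signed step) boundaries into segments."""
    sp = cfg.probe_spacing
    rows = []
    for c in range(1, cfg.n_chromosomes + 1):
        chrom = str(c)
        bnds = sorted(boundaries.get(chrom, []))
        probes = [0] + [b for b, _ in bnds] + [cfg.probes_per_chromosome]
        mean = 0.0
        steps = [s for _, s in bnds]
        for i in range(len(probes) - 1):
            lo, hi = probes[i], probes[i + 1]
            if i > 0:
                mean += steps[i - 1]
            rows.append({
                "sample_id": sample, "chromosome": chrom,
                "start": lo * sp + 1, "end": hi * sp,
                "num_probes": hi - lo, "segment_mean": round(mean, 6),
            })
    return rows


def simulate_copy_number_cohort(cfg: SimulationConfig):
    """Simulate tumor and normal-panel SEG tables plus ground truth.

    Returns ``(tumor_seg, normal_seg, truth)``. Every planted somatic
    break is a segment boundary with a step of at least 0.2 and flanks
    of at least 20 probes; artifact breaks violate at least one filter;
    every germline site appears at identical coordinates in at least one
    normal-panel sample.
    """
    sp = cfg.probe_spacing
    slots = cfg.slots()
    g_rng = _rng(cfg.seed, "germline")
    s_rng = _rng(cfg.seed, "segments")

    germ_idx = g_rng.choice(len(slots), size=cfg.n_germline_sites, replace=False) \
        if cfg.n_germline_sites else np.array([], dtype=int)
    germline_sites = [slots[i] for i in sorted(germ_idx)]
    free_slots = [s for i, s in enumerate(slots) if i not in set(germ_idx.tolist())]

    # per-sample covariates drawn first: they shape the break rate
    sample_ids = cfg.sample_ids
    n = len(sample_ids)
    cancer_type = np.repeat(list(cfg.cancer_types), cfg.n_samples)
    stage = s_rng.choice(["I", "II", "III", "IV"], size=n, p=list(cfg.stage_probs))
    msi = s_rng.random(n) < cfg.msi_fraction
    driver_status = pd.DataFrame(
        {g: s_rng.random(n) < cfg.driver_altered_fraction for g in cfg.driver_genes},
        index=pd.Index(sample_ids, name="sample_id"), dtype=bool,
    )

    stage_ord = np.array([{"I": 0, "II": 1, "III": 2, "IV": 3}[s] for s in stage])
    rate_mult = (1.0 + cfg.stage_tbl_shift * stage_ord)
    rate_mult = rate_mult * np.where(msi, cfg.msi_tbl_multiplier, 1.0)
    if len(cfg.driver_genes):
        any_driver = driver_status.to_numpy().any(axis=1)
        rate_mult = rate_mult * np.where(any_driver, cfg.driver_tbl_multiplier, 1.0)

    tumor_rows: list[dict] = []
    events: dict[str, list] = {}
    somatic: dict[str, list] = {}
    artifacts: dict[str, list] = {}
    germline: dict[str, list] = {}

    for i, sample in enumerate(sample_ids):
        n_breaks = _draw_break_count(cfg, s_rng, rate_mult[i])
        n_art = int(s_rng.poisson(cfg.artifact_break_mean))
        if n_breaks + n_art > len(free_slots):
            raise ConfigError(
                f"sample {sample}: {n_breaks} somatic + {n_art} artifact breaks "
                f"exceed the {len(free_slots)} available break slots; "
                "use longer or more chromosomes"
            )
        order = s_rng.permutation(len(free_slots))
        take = iter(order)
        som_slots = sorted(free_slots[next(take)] for _ in range(n_breaks))

        boundaries: dict[str, list[tuple[int, float]]] = {}
        ev_list, som_list, art_list = [], [], []

        # pair somatic slots within chromosomes into unbalanced events
        by_chrom: dict[str, list[int]] = {}
        for chrom, b in som_slots:
            by_chrom.setdefault(chrom, []).append(b)
        for chrom, bs in by_chrom.items():
            bs = sorted(bs)
            k = 0
            while k + 1 < len(bs):
                lo, hi = bs[k], bs[k + 1]
                mag = _step(cfg, s_rng)
                sign = 1.0 if s_rng.random() < 0.5 else -1.0
                boundaries.setdefault(chrom, []).extend([(lo, sign * mag), (hi, -sign * mag)])
                ev_list.append((chrom, lo * sp, hi * sp, "DUP" if sign > 0 else "DEL"))
                som_list += [(chrom, lo * sp), (chrom, hi * sp)]
                k += 2
            if k < len(bs):  # singleton break: one-sided unbalanced event
                b = bs[k]
                mag = _step(cfg, s_rng)
                sign = 1.0 if s_rng.random() < 0.5 else -1.0
                boundaries.setdefault(chrom, []).append((b, sign * mag))
                ev_list.append((chrom, b * sp, None, "DUP" if sign > 0 else "DEL"))
                som_list.append((chrom, b * sp))

        # artifacts: small-step singletons or small-flank pairs
        remaining = n_art
        while remaining > 0:
            chrom, b = free_slots[next(take)]
            if remaining >= 2 and s_rng.random() < 0.5:
                mag = _step(cfg, s_rng)
                boundaries.setdefault(chrom, []).extend(
                    [(b, mag), (b + cfg.artifact_flank_probes, -mag)])
                art_list += [(chrom, b * sp), (chrom, (b + cfg.artifact_flank_probes) * sp)]
                remaining -= 2
            else:
                mag = float(s_rng.uniform(*cfg.artifact_step_range))
                sign = 1.0 if s_rng.random() < 0.5 else -1.0
                boundaries.setdefault(chrom, []).append((b, sign * mag))
                art_list.append((chrom, b * sp))
                remaining -= 1

        # germline sites carried by this tumor
        germ_list = []
        for chrom, b in germline_sites:
            if s_rng.random() < cfg.germline_sample_prob:
                mag = _step(cfg, s_rng)
                sign = 1.0 if s_rng.random() < 0.5 else -1.0
                boundaries.setdefault(chrom, []).append((b, sign * mag))
                germ_list.append((chrom, b * sp))

        tumor_rows += _segments_from_boundaries(sample, cfg, boundaries)
        events[sample] = ev_list
        somatic[sample] = sorted(som_list)
        artifacts[sample] = sorted(art_list)
        germline[sample] = sorted(germ_list)

    # normal panel: carries the germline sites (each site in >= 1 normal)
    normal_rows: list[dict] = []
    for j in range(cfg.n_normals):
        sample = f"N{j + 1:04d}"
        boundaries = {}
        for k, (chrom, b) in enumerate(germline_sites):
            forced = (k % max(cfg.n_normals, 1)) == j
            if forced or s_rng.random() < 0.5:
                mag = float(s_rng.uniform(0.05, 0.4))
                sign = 1.0 if s_rng.random() < 0.5 else -1.0
                boundaries.setdefault(chrom, []).append((b, sign * mag))
        normal_rows += _segments_from_boundaries(sample, cfg, boundaries)

    tumor_seg = io_formats.sort_seg(pd.DataFrame(tumor_rows))
    normal_seg = io_formats.sort_seg(pd.DataFrame(normal_rows)) if normal_rows else \
        pd.DataFrame(columns=io_formats.SEG_COLUMNS)

    samples = pd.DataFrame({
        "sample_id": sample_ids,
        "cancer_type": cancer_type,
        "stage": stage,
        "msi": msi,
        "n_somatic_breaks": [len(somatic[s]) for s in sample_ids],
    })
    samples["tbl_group"] = _quartile_groups(samples)

    truth = GroundTruth(
        samples=samples, events=events, somatic_breaks=somatic,
        artifact_breaks=artifacts, germline_breaks=germline,
        germline_sites=germline_sites, driver_status=driver_status,
    )
    return tumor_seg, normal_seg, truth


def _quartile_groups(samples: pd.DataFrame) -> np.ndarray:
    """Label the top quartile of true break counts HIGH, bottom LOW, per type."""
    out = np.array(["INTERMEDIATE"] * len(samples), dtype=object)
    for ct, grp in samples.groupby("cancer_type"):
        q = len(grp) // 4
        order = grp.sort_values(["n_somatic_breaks", "sample_id"],
                                ascending=[False, True]).index
        if q:
            out[samples.index.get_indexer(order[:q])] = "HIGH"
            out[samples.index.get_indexer(order[-q:])] = "LOW"
    return out


# ---------------------------------------------------------------------------
# SV calls


def simulate_sv_calls(truth: GroundTruth, cfg: SimulationConfig) -> pd.DataFrame:
    """Emit a BEDPE call set: one DEL/DUP per planted unbalanced event,
    plus balanced INV/TRA decoys from an independent substream.

    For singleton breaks the far breakpoint falls one probe spacing
    downstream (between probes, invisible to the array). Decoys come
    from the ``decoy_seed`` stream, so changing only that seed leaves
    the DEL/DUP records identical.
    """
    sp = cfg.probe_spacing
    rng = _rng(cfg.decoy_seed if cfg.decoy_seed is not None else cfg.seed, "sv_decoys")
    rows = []
    for sample in truth.samples["sample_id"]:
        for chrom, lo, hi, svt in truth.events[sample]:
            hi = lo + sp if hi is None else hi
            rows.append({
                "sample_id": sample,
                "chrom1": chrom, "start1": lo, "end1": lo + 1,
                "chrom2": chrom, "start2": hi, "end2": hi + 1,
                "sv_type": svt, "filter_pass": True,
            })
        for _ in range(rng.poisson(cfg.sv_decoy_mean)):
            svt = "INV" if rng.random() < 0.5 else "TRA"
            c1 = str(rng.integers(1, cfg.n_chromosomes + 1))
            c2 = c1 if svt == "INV" else str(rng.integers(1, cfg.n_chromosomes + 1))
            p1 = int(rng.integers(1, cfg.chromosome_length - sp))
            p2 = int(rng.integers(1, cfg.chromosome_length - sp))
            if svt == "INV" or c1 == c2:
                svt = "INV" if c1 == c2 else "TRA"
                p1, p2 = min(p1, p2), max(p1, p2)
            rows.append({
                "sample_id": sample,
                "chrom1": c1, "start1": p1, "end1": p1 + 1,
                "chrom2": c2, "start2": p2, "end2": p2 + 1,
                "sv_type": svt,
                "filter_pass": bool(rng.random() >= cfg.sv_decoy_fail_fraction),
            })
    cols = ["sample_id", "chrom1", "start1", "end1", "chrom2", "start2", "end2",
            "sv_type", "filter_pass"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# mutations


def simulate_gene_map(cfg: SimulationConfig) -> pd.DataFrame:
    """Deterministic gene coordinate table (1-based inclusive intervals)."""
    rows = []
    per_chrom = math.ceil(cfg.n_mutation_genes / cfg.n_chromosomes)
    pitch = max(cfg.chromosome_length // (per_chrom + 1), cfg.gene_length + 1)
    for g in range(cfg.n_mutation_genes):
        chrom = str(g % cfg.n_chromosomes + 1)
        slot = g // cfg.n_chromosomes
        start = slot * pitch + 1
        end = min(start + cfg.gene_length - 1, cfg.chromosome_length)
        rows.append({"gene": f"G{g + 1:04d}", "chromosome": chrom,
                     "start": start, "end": end})
    return pd.DataFrame(rows)


def simulate_mutations(truth: GroundTruth, cfg: SimulationConfig,
                       genes: pd.DataFrame | None = None) -> pd.DataFrame:
    """MAF-like table: background SNVs with an MSI excess, plus one
    guaranteed non-silent SNV in each driver gene of each altered sample.

    Driver genes are excluded from the background pool so that the
    alteration flag derived from this table equals the planted status.
    """
    if genes is None:
        genes = simulate_gene_map(cfg)
    rng = _rng(cfg.seed, "mutations")
    background = genes[~genes["gene"].isin(cfg.driver_genes)].reset_index(drop=True)
    classes = ["Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del"]
    rows = []
    msi = dict(zip(truth.samples["sample_id"], truth.samples["msi"]))
    for sample in truth.samples["sample_id"]:
        mean = cfg.tmb_mean * (cfg.msi_tmb_multiplier if msi[sample] else 1.0)
        r = 1.0 / max(cfg.tmb_dispersion, 1e-8)
        n_mut = int(rng.negative_binomial(r, r / (r + mean))) if mean > 0 else 0
        idx = rng.integers(0, len(background), size=n_mut)
        for k in idx:
            g = background.iloc[int(k)]
            silent = rng.random() < cfg.silent_fraction
            rows.append({
                "sample_id": sample, "gene": g["gene"], "chromosome": g["chromosome"],
                "position": int(rng.integers(g["start"], g["end"] + 1)),
                "variant_classification": io_formats.SILENT_CLASS if silent
                else classes[int(rng.integers(0, len(classes)))],
            })
        for gname in cfg.driver_genes:
            if truth.driver_status.loc[sample, gname]:
                g = genes[genes["gene"] == gname].iloc[0]
                rows.append({
                    "sample_id": sample, "gene": gname, "chromosome": g["chromosome"],
                    "position": int(rng.integers(g["start"], g["end"] + 1)),
                    "variant_classification": "Missense_Mutation",
                })
    return pd.DataFrame(rows, columns=io_formats.MUTATION_COLUMNS)


# ---------------------------------------------------------------------------
# expression


def simulate_expression(is_high, cfg: SimulationConfig,
                        rng: np.random.Generator | None = None):
    """Gene-by-sample raw counts from a negative-binomial model.

    ``is_high`` is a boolean series (index = sample ids) marking the
    high-burden arm. Exactly ``round(de_fraction * n_genes)`` genes
    carry a nonzero log2 effect in the high arm; signs are balanced at
    random. Returns ``(counts, gene_truth)``.
    """
    is_high = pd.Series(is_high).astype(bool)
    if rng is None:
        rng = _rng(cfg.seed, "expression")
    n_genes, n_samples = cfg.n_genes, len(is_high)
    genes = [f"ENSG{g + 1:05d}" for g in range(n_genes)]
    base = np.exp(rng.normal(cfg.expr_base_log_mean, cfg.expr_base_log_sd, size=n_genes))
    n_de = int(round(cfg.de_fraction * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    lfc = np.zeros(n_genes)
    lo, hi = cfg.de_log2fc_range
    lfc[de_idx] = rng.uniform(lo, hi, size=n_de) * rng.choice([-1.0, 1.0], size=n_de)
    lib = np.exp(rng.normal(0.0, cfg.expr_libsize_log_sd, size=n_samples))

    mean = base[:, None] * lib[None, :]
    mean = mean * np.power(2.0, lfc[:, None] * is_high.to_numpy()[None, :])
    alpha = cfg.expr_dispersion
    if alpha < 1e-8:
        counts = rng.poisson(mean)
    else:
        r = 1.0 / alpha
        counts = rng.negative_binomial(r, r / (r + mean))
    counts = pd.DataFrame(counts.astype(np.int64), index=pd.Index(genes, name="gene"),
                          columns=list(is_high.index))
    gene_truth = pd.DataFrame({"gene": genes, "is_de": lfc != 0.0, "log2fc": lfc})
    return counts, gene_truth


# ---------------------------------------------------------------------------
# clinical


def simulate_clinical(truth: GroundTruth, cfg: SimulationConfig,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Clinical table with proportional-hazards survival linkage.

    The hazard for samples in the high-burden quartile is multiplied by
    ``true_hr_high`` for both endpoints; censoring is independent
    exponential, calibrated so that a fraction ``censoring_rate`` of a
    baseline-hazard sample would be censored first.
    """
    if rng is None:
        rng = _rng(cfg.seed, "clinical")
    s = truth.samples
    n = len(s)
    high = (s["tbl_group"] == "HIGH").to_numpy()
    hazard = cfg.baseline_hazard * np.where(high, cfg.true_hr_high, 1.0)

    c = cfg.censoring_rate
    cens_rate = cfg.baseline_hazard * c / (1.0 - c) if c > 0 else 0.0

    def _endpoint():
        t_event = rng.exponential(1.0 / hazard)
        t_cens = rng.exponential(1.0 / cens_rate, size=n) if cens_rate > 0 \
            else np.full(n, np.inf)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        return np.round(time, 1), event

    os_time, os_event = _endpoint()
    dfs_time, dfs_event = _endpoint()
    return pd.DataFrame({
        "sample_id": s["sample_id"],
        "cancer_type": s["cancer_type"],
        "age": np.round(rng.normal(65.0, 10.0, size=n), 1),
        "sex": rng.choice(["male", "female"], size=n),
        "stage": s["stage"],
        "msi_status": np.where(s["msi"], "MSI", "MSS"),
        "treated": rng.random(n) < 0.3,
        "os_time": os_time, "os_event": os_event,
        "dfs_time": dfs_time, "dfs_event": dfs_event,
    })


# ---------------------------------------------------------------------------
# orchestration


def simulate_cohort(cfg: SimulationConfig, audit: bool = True) -> Cohort:
    """Simulate a full cohort (segments, SVs, mutations, expression,
    clinical) and self-audit the files against the recorded truth."""
    tumor_seg, normal_seg, truth = simulate_copy_number_cohort(cfg)
    genes = simulate_gene_map(cfg)
    sv = simulate_sv_calls(truth, cfg)
    mutations = simulate_mutations(truth, cfg, genes)
    is_high = pd.Series((truth.samples["tbl_group"] == "HIGH").to_numpy(),
                        index=truth.samples["sample_id"])
    counts, gene_truth = simulate_expression(is_high, cfg)
    clinical = simulate_clinical(truth, cfg)
    truth.gene_truth = gene_truth
    truth.true_hr = cfg.true_hr_high
    cohort = Cohort(cfg, tumor_seg, normal_seg, sv, mutations, genes, counts,
                    clinical, truth)
    if audit:
        audit_cohort(cohort)
    return cohort


def audit_cohort(cohort: Cohort) -> None:
    """Verify truth/file consistency; raises :class:`AuditError` on failure."""
    cfg = cohort.config
    seg = cohort.tumor_seg
    for sample, grp in seg.groupby("sample_id"):
        boundaries = {}
        for chrom, cgrp in grp.groupby("chromosome"):
            cgrp = cgrp.sort_values("start")
            ends = cgrp["end"].to_numpy()[:-1]
            steps = np.abs(np.diff(cgrp["segment_mean"].to_numpy()))
            flanks = np.minimum(cgrp["num_probes"].to_numpy()[:-1],
                                cgrp["num_probes"].to_numpy()[1:])
            for e, st, fl in zip(ends, steps, flanks):
                boundaries[(chrom, int(e))] = (st, fl)
        for chrom, pos in cohort.truth.somatic_breaks.get(sample, []):
            key = (chrom, int(pos))
            if key not in boundaries:
                raise AuditError(f"{sample}: somatic break {key} has no segment boundary")
            st, fl = boundaries[key]
            if st < 0.135 - 1e-9 or fl < 20:
                raise AuditError(f"{sample}: somatic break {key} would be filtered "
                                 f"(step {st:.3f}, flank {fl})")
        for chrom, pos in cohort.truth.artifact_breaks.get(sample, []):
            st, fl = boundaries[(chrom, int(pos))]
            if st >= 0.135 and fl >= 20:
                raise AuditError(f"{sample}: artifact break at {(chrom, pos)} "
                                 "violates no filter")
    sp = cfg.probe_spacing
    normal_bounds = set()
    for _, row in cohort.normal_seg.iterrows():
        normal_bounds.add((row["chromosome"], int(row["end"])))
    for chrom, b in cohort.truth.germline_sites:
        if cfg.n_normals and (chrom, b * sp) not in normal_bounds:
            raise AuditError(f"germline site {(chrom, b * sp)} absent from the normal panel")
    n_de = int(round(cfg.de_fraction * cfg.n_genes))
    if cohort.truth.gene_truth is not None and \
            int(cohort.truth.gene_truth["is_de"].sum()) != n_de:
        raise AuditError("differentially-expressed gene count does not match config")


def write_cohort(cohort: Cohort, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    io_formats.write_seg(cohort.tumor_seg, out / "tumor.seg")
    io_formats.write_seg(cohort.normal_seg, out / "normals.seg")
    io_formats.write_bedpe(cohort.sv, out / "svs.bedpe")
    io_formats.write_mutations(cohort.mutations, out / "mutations.tsv")
    io_formats.write_counts(cohort.counts, out / "counts.tsv")
    io_formats.write_clinical(cohort.clinical, out / "clinical.tsv")
    cohort.genes.to_csv(out / "genes.bed", sep="\t", index=False)
    cohort.truth.to_json(out / "truth.json")
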