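"""Synthetic study generator with known ground truth.

Emits every input the pipeline consumes: pesticide application records in the
style of California Pesticide Use Reporting (chemical code, year, pounds,
acres, planar location), participant address histories, a covariate table, a
beta-value matrix with annotation and QC flags, and gene-set definitions.

The stated world mirrors the population the method was developed for: an
agricultural case-control cohort (default 569 cases / 237 controls; cases
about three years older; 59.8% male; 86.2% European ancestry; smoking
49.3/45.4/5.3% never/former/current; two recruitment waves), with copper and
organophosphate applications sharing spatial hotspots so the two exposure
counts are strongly positively correlated — the central confounding structure
the OP adjustment exists to address.

Methylation is generated on the logit (M-value) scale, where covariate and
exposure effects are additive, and mapped through the inverse logit so beta
values are strictly inside (0, 1).  Planted probe effects are calibrated
analytically so that the partial correlation between adjusted methylation and
the copper count — the quantity the downstream EWAS measures — matches the
requested ``effect_size_r``: the copper count is projected onto the
adjustment design and the slope is chosen as
``b = r / sqrt(1 - r^2) * noise_sd / sd(copper_perp)``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from . import exposure as exposure_mod
from .enrichment import GeneSet
from .preprocess import CELL_TYPES, build_design

logger = logging.getLogger(__name__)

#: blood cell mixture concentration (Dirichlet), roughly whole-blood like:
#: CD8T, CD4T, NK, B, monocytes, granulocytes
_CELL_ALPHA = np.array([0.06, 0.14, 0.06, 0.05, 0.08, 0.61]) * 60.0

_ENRICH_CATEGORIES = ("BP", "CC", "MF", "pathway")

#: Effects are planted on the logit scale but measured (as bicor) on the
#: winsorized beta scale; the inverse-logit curvature and the 5/95
#: winsorization attenuate the realized correlation by ~13%.  The planting
#: scale compensates by this fixed, once-calibrated factor so the realized
#: partial correlation matches effect_size_r.
EFFECT_ATTENUATION = 0.87


def copper_codes(n: int = 15) -> tuple[int, ...]:
    """CADPR-style chemical codes for the copper group."""
    return tuple(range(1001, 1001 + n))


def op_codes(n: int = 40) -> tuple[int, ...]:
    """CADPR-style chemical codes for the organophosphate group."""
    return tuple(range(2001, 2001 + n))


@dataclass(frozen=True)
class DmrSpec:
    """One region to plant: ``n_probes`` consecutive clean probes on
    ``chromosome`` at/after ``start`` shifted by ``shift`` (logit scale) per
    unit copper count; ``shift=None`` uses the calibrated single-probe slope."""

    chromosome: str
    start: int
    n_probes: int
    shift: float | None = None


@dataclass(frozen=True)
class SimulationConfig:
    n_cases: int = 569
    n_controls: int = 237
    n_probes: int = 20000
    n_chemicals_copper: int = 15
    n_chemicals_op: int = 40
    years: tuple[int, int] = (1974, 2015)
    region_extent: float = 20000.0          # square side, meters
    n_applications_per_year: int = 400
    n_hotspots: int = 25
    effect_probes: int = 0
    effect_size_r: float = 0.3
    dmr_specs: tuple[DmrSpec, ...] = ()
    covariate_effect_sizes: Mapping[str, float] = field(
        default_factory=lambda: {
            "age": 0.10, "sex": 0.10, "ancestry": 0.05, "smoking": 0.05,
            "wave": 0.10, "op_count": 0.05, "cell": 0.30,
        }
    )
    noise_sd: float = 0.5                   # residual SD, logit scale
    flag_fraction: float = 0.28             # fraction of probes carrying a QC flag
    median_gap_bp: int = 500
    age_shift: float = 3.1                  # case-minus-control mean age, years
    seed: int = 0

    def __post_init__(self):
        for name in ("n_cases", "n_controls", "n_probes", "n_chemicals_copper",
                     "n_chemicals_op", "n_hotspots"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_applications_per_year < 0:
            raise ValueError("n_applications_per_year must be >= 0")
        if not (0 < self.effect_size_r < 1):
            raise ValueError("effect_size_r must lie in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.years[0] > self.years[1] or self.years[0] > 1974:
            raise ValueError("years must be an increasing range starting at/before 1974")
        if not (0 <= self.flag_fraction < 1):
            raise ValueError("flag_fraction must lie in [0, 1)")
        dmr_total = sum(s.n_probes for s in self.dmr_specs)
        if self.effect_probes + dmr_total > self.n_probes:
            raise ValueError("effect_probes + DMR probes exceed n_probes")

    @property
    def copper_codes(self) -> tuple[int, ...]:
        return copper_codes(self.n_chemicals_copper)

    @property
    def op_codes(self) -> tuple[int, ...]:
        return op_codes(self.n_chemicals_op)


@dataclass
class GroundTruth:
    """What was planted, recorded so recovery tests never re-derive it."""

    planted_probe_ids: list
    probe_slopes: dict                      # probe id -> logit-scale slope
    planted_regions: list                   # dicts: chromosome/start/end/probe_ids/shift
    copper_counts: dict                     # participant -> count used in planting
    op_counts: dict
    effect_size_r: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _hotspots(config: SimulationConfig):
    """Shared agricultural hotspots: locations plus copper/OP intensity weights.

    OP intensity is a noisy log-linear function of copper intensity, so the
    two chemical groups share spatial structure and downstream counts
    correlate positively.
    """
    rng = np.random.default_rng([config.seed, 90])
    xy = rng.uniform(0, config.region_extent, size=(config.n_hotspots, 2))
    copper_w = rng.lognormal(0.0, 1.0, config.n_hotspots)
    op_w = copper_w * np.exp(rng.normal(0.0, 0.4, config.n_hotspots))
    return xy, copper_w / copper_w.sum(), op_w / op_w.sum()


def generate_applications(config: SimulationConfig) -> pd.DataFrame:
    """Application records spanning ``config.years``.

    Each year, half the events are copper-group and half OP-group chemicals;
    the hotspot an event lands near is drawn from the group's intensity
    weights, and the location is the hotspot plus isotropic scatter (field
    positions around a farm center).
    """
    rng = np.random.default_rng([config.seed, 1])
    xy, copper_w, op_w = _hotspots(config)
    rows = {"chemical_code": [], "year": [], "pounds": [], "acres": [],
            "x": [], "y": []}
    n_per_year = config.n_applications_per_year
    n_cu = n_per_year // 2
    for year in range(config.years[0], config.years[1] + 1):
        for n_grp, weights, codes in (
            (n_cu, copper_w, config.copper_codes),
            (n_per_year - n_cu, op_w, config.op_codes),
        ):
            if n_grp == 0:
                continue
            hs = rng.choice(config.n_hotspots, size=n_grp, p=weights)
            loc = xy[hs] + rng.normal(0.0, 1000.0, size=(n_grp, 2))
            rows["chemical_code"].extend(rng.choice(codes, size=n_grp).tolist())
            rows["year"].extend([year] * n_grp)
            rows["pounds"].extend(rng.lognormal(3.0, 1.0, n_grp).tolist())
            rows["acres"].extend(rng.lognormal(0.7, 0.5, n_grp).tolist())
            rows["x"].extend(loc[:, 0].tolist())
            rows["y"].extend(loc[:, 1].tolist())
    return pd.DataFrame(rows)


def _draw_location(rng, config, xy) -> np.ndarray:
    """Participant location: usually near a hotspot, sometimes anywhere."""
    if rng.random() < 0.6:
        center = xy[rng.integers(len(xy))]
        return center + rng.normal(0.0, 1500.0, 2)
    return rng.uniform(0, config.region_extent, 2)


def generate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Address histories and a covariate table for the synthetic cohort.

    Address intervals tile 1974 through the blood-draw year (one to three
    residential intervals; 30% of participants also hold a workplace
    address over a sub-window).  Covariates reproduce the demographic
    structure of the target population; the six cell-composition fractions
    sum to one by construction (Dirichlet).
    """
    rng = np.random.default_rng([config.seed, 2])
    xy, *_ = _hotspots(config)
    n = config.n_cases + config.n_controls
    pids = [f"P{i + 1:04d}" for i in range(n)]
    pd_status = np.array([1] * config.n_cases + [0] * config.n_controls)

    wave = np.where(rng.random(n) < 0.55, "PEG1", "PEG2")
    age = rng.normal(67.4 + config.age_shift * pd_status, 11.0).clip(35, 95)
    sex = np.where(rng.random(n) < 0.598, "M", "F")
    ancestry = (rng.random(n) < 0.862).astype(int)
    smoking = rng.choice(["never", "former", "current"], size=n,
                         p=[0.493, 0.454, 0.053])
    # guarantee every categorical level occurs within each disease stratum,
    # so adjustment designs stay full rank even in small or stratified runs
    for status in (0, 1):
        idx = np.flatnonzero(pd_status == status)
        for pos, level in zip(idx, ("never", "former", "current")):
            smoking[pos] = level
        for pos, level in zip(idx, ("M", "F")):
            sex[pos] = level
        for pos, level in zip(idx, ("PEG1", "PEG2")):
            wave[pos] = level
        for pos, level in zip(idx, (0, 1)):
            ancestry[pos] = level
    draw_year = np.where(wave == "PEG1",
                         rng.integers(2000, 2008, n),
                         rng.integers(2010, min(2016, config.years[1] + 1), n))
    cells = rng.dirichlet(_CELL_ALPHA, size=n)

    addr_rows = {k: [] for k in exposure_mod.ADDRESS_COLUMNS}

    def _add(pid, loc, y0, y1, kind):
        addr_rows["participant_id"].append(pid)
        addr_rows["x"].append(float(loc[0]))
        addr_rows["y"].append(float(loc[1]))
        addr_rows["start_year"].append(int(y0))
        addr_rows["end_year"].append(int(y1))
        addr_rows["kind"].append(kind)

    for i, pid in enumerate(pids):
        y_end = int(draw_year[i])
        n_res = int(rng.integers(1, 4))
        cuts = np.sort(rng.choice(np.arange(1975, y_end), size=n_res - 1,
                                  replace=False)) if n_res > 1 else np.array([], int)
        bounds = [1974, *cuts.tolist(), y_end + 1]
        for j in range(n_res):
            _add(pid, _draw_location(rng, config, xy), bounds[j],
                 bounds[j + 1] - 1, "residential")
        if rng.random() < 0.3:
            w0 = int(rng.integers(1974, y_end + 1))
            w1 = int(rng.integers(w0, y_end + 1))
            _add(pid, _draw_location(rng, config, xy), w0, w1, "workplace")

    covariates = pd.DataFrame(
        {
            "pd_status": pd_status,
            "age": age,
            "sex": sex,
            "ancestry": ancestry,
            "smoking": smoking,
            "wave": wave,
            **{cell: cells[:, k] for k, cell in enumerate(CELL_TYPES)},
            "blood_draw_year": draw_year,
        },
        index=pd.Index(pids, name="participant_id"),
    )
    return pd.DataFrame(addr_rows), covariates


def _generate_annotation(config: SimulationConfig, rng) -> pd.DataFrame:
    """Probe layout on 22 autosomes + X/Y: sorted positions with a median
    inter-probe gap of ``median_gap_bp``, gene blocks of consecutive probes,
    and QC flags on ≈ ``flag_fraction`` of probes (sex-chromosome probes are
    always flagged)."""
    chroms = [str(i) for i in range(1, 23)] + ["X", "Y"]
    w = np.array([1 / np.sqrt(i) for i in range(1, 23)] + [0.25, 0.08])
    w = w / w.sum()
    counts = np.floor(w * config.n_probes).astype(int)
    counts[0] += config.n_probes - counts.sum()

    mean_gap = config.median_gap_bp / np.log(2)  # exponential gaps: stated median
    chrom_col, pos_col, gene_col = [], [], []
    gene_counter = 0
    for chrom, cnt in zip(chroms, counts):
        gaps = 1 + np.floor(rng.exponential(mean_gap, cnt)).astype(np.int64)
        pos = 10_000 + np.cumsum(gaps)
        chrom_col.extend([chrom] * cnt)
        pos_col.extend(pos.tolist())
        done = 0
        while done < cnt:
            block = min(int(rng.geometric(1 / 8)), 40, cnt - done)
            if rng.random() < 0.15:
                gene_col.extend([""] * block)
            else:
                gene_counter += 1
                gene_col.extend([f"GENE{gene_counter:05d}"] * block)
            done += block

    n = config.n_probes
    sex_chrom = np.isin(chrom_col, ["X", "Y"])
    n_sex = int(sex_chrom.sum())
    q = max(0.0, (config.flag_fraction * n - n_sex) / max(n - n_sex, 1))
    flagged = (~sex_chrom) & (rng.random(n) < q)
    flag_choice = rng.choice(["cross_reactive", "snp", "non_cpg"], size=n,
                             p=[0.5, 0.35, 0.15])
    flags = np.where(sex_chrom, "sex_chromosome", np.where(flagged, flag_choice, ""))

    probe_ids = [f"cg{i + 1:08d}" for i in range(n)]
    return pd.DataFrame(
        {
            "chromosome": chrom_col,
            "position": np.asarray(pos_col, dtype=np.int64),
            "gene": gene_col,
            "flags": flags,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )


def _resolve_dmr_run(annot: pd.DataFrame, spec: DmrSpec, max_gap_bp: int = 1000):
    """First run of ``spec.n_probes`` consecutive unflagged probes on the
    chromosome at/after ``spec.start`` with successive gaps <= max_gap_bp."""
    sub = annot[(annot["chromosome"] == spec.chromosome) & (annot["flags"] == "")]
    sub = sub.sort_values("position", kind="mergesort")
    pos = sub["position"].to_numpy()
    k = spec.n_probes
    for i in range(len(sub) - k + 1):
        if pos[i] < spec.start:
            continue
        if np.all(np.diff(pos[i : i + k]) <= max_gap_bp):
            return list(sub.index[i : i + k])
    raise ValueError(
        f"no eligible run of {k} probes on chromosome {spec.chromosome} "
        f"at/after position {spec.start}"
    )


def generate_beta_matrix(
    config: SimulationConfig,
    counts: pd.DataFrame,
    covariates: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Beta matrix (probes x samples), annotation, and ground truth.

    ``counts`` must carry ``copper_count`` and ``op_count`` for exactly the
    participants in ``covariates``.  Effects are additive on the logit scale;
    planted slopes are calibrated against the copper count's residual
    variance after projection onto the adjustment design, so the planted
    partial correlation matches ``effect_size_r``.
    """
    if not counts.index.equals(covariates.index):
        if set(counts.index) != set(covariates.index):
            raise ValueError("counts and covariates must cover the same participants")
        counts = counts.loc[covariates.index]
    rng = np.random.default_rng([config.seed, 3])
    annot = _generate_annotation(config, rng)

    cov = covariates.copy()
    cov["op_count"] = counts["op_count"]
    X, _ = build_design(cov)
    c = counts["copper_count"].to_numpy(float)
    coef, *_ = np.linalg.lstsq(X, c, rcond=None)
    c_perp = c - X @ coef
    sd_perp = float(c_perp.std())
    if sd_perp < 1e-9:
        raise ValueError("copper count has no variance beyond the covariates; "
                         "cannot calibrate planted effects")
    r = min(config.effect_size_r / EFFECT_ATTENUATION, 0.99)
    b_cal = r / np.sqrt(1 - r**2) * config.noise_sd / sd_perp

    # resolve planted regions first, then draw single-probe effects elsewhere
    regions = []
    region_probes: set = set()
    for spec in config.dmr_specs:
        run = _resolve_dmr_run(annot, spec)
        shift = float(spec.shift) if spec.shift is not None else float(
            b_cal * (1 if rng.random() < 0.5 else -1)
        )
        regions.append(
            {
                "chromosome": spec.chromosome,
                "start": int(annot.loc[run[0], "position"]),
                "end": int(annot.loc[run[-1], "position"]),
                "probe_ids": run,
                "shift": shift,
            }
        )
        region_probes.update(run)

    clean = annot.index[(annot["flags"] == "")
                        & ~annot["chromosome"].isin(["X", "Y"])
                        & ~annot.index.isin(list(region_probes))]
    if config.effect_probes > len(clean):
        raise ValueError("not enough clean probes to plant effect_probes")
    planted = list(rng.choice(clean, size=config.effect_probes, replace=False)) \
        if config.effect_probes else []
    signs = rng.choice([-1.0, 1.0], size=len(planted))

    n_probes, n = config.n_probes, len(cov)
    slope_vec = pd.Series(0.0, index=annot.index)
    slope_vec.loc[planted] = signs * b_cal
    for reg in regions:
        slope_vec.loc[reg["probe_ids"]] = reg["shift"]

    # baseline logit methylation: unmethylated / methylated / intermediate
    comp = rng.choice(3, size=n_probes, p=[0.45, 0.35, 0.20])
    mu = np.where(comp == 0, rng.normal(-2.2, 0.7, n_probes),
                  np.where(comp == 1, rng.normal(2.2, 0.7, n_probes),
                           rng.normal(0.0, 1.0, n_probes)))

    # standardized covariate columns with per-probe random slopes
    eff = dict(config.covariate_effect_sizes)
    def _std(v):
        v = np.asarray(v, float)
        s = v.std()
        return (v - v.mean()) / s if s > 0 else np.zeros_like(v)
    z_cols = {
        "age": _std(cov["age"]), "sex": _std(cov["sex"] == "M"),
        "ancestry": _std(cov["ancestry"]),
        "smoking": _std(cov["smoking"].map({"never": 0, "former": 1, "current": 2})),
        "wave": _std(cov["wave"] == "PEG2"),
        "op_count": _std(cov["op_count"]),
    }
    Z = np.column_stack(list(z_cols.values())
                        + [_std(cov[cell]) for cell in CELL_TYPES])
    gamma_sd = np.array([eff[k] for k in z_cols] + [eff["cell"]] * len(CELL_TYPES))
    gamma = rng.normal(0.0, 1.0, size=(n_probes, Z.shape[1])) * gamma_sd[None, :]

    M = (mu[:, None] + gamma @ Z.T
         + slope_vec.to_numpy()[:, None] * c[None, :]
         + rng.normal(0.0, config.noise_sd, size=(n_probes, n)))
    beta = pd.DataFrame(expit(M), index=annot.index, columns=cov.index)

    truth = GroundTruth(
        planted_probe_ids=list(planted),
        probe_slopes={p: float(s) for p, s in
                      slope_vec[slope_vec != 0].items()},
        planted_regions=regions,
        copper_counts={p: int(v) for p, v in counts["copper_count"].items()},
        op_counts={p: int(v) for p, v in counts["op_count"].items()},
        effect_size_r=r,
    )
    return beta, annot, truth


def generate_gene_sets(
    annot: pd.DataFrame,
    n_sets: int = 200,
    set_size: tuple[int, int] = (10, 80),
    planted_genes: Sequence[str] | None = None,
    seed: int = 0,
) -> dict[str, GeneSet]:
    """Random gene sets over the annotation's gene universe (GMT-style).

    Category labels cycle through BP/CC/MF/pathway.  When ``planted_genes``
    is given, the first set is built from them (a truly enriched set for
    recovery tests).
    """
    rng = np.random.default_rng([seed, 7])
    genes = sorted({g.upper() for g in annot["gene"] if g})
    sets: dict[str, GeneSet] = {}
    if planted_genes:
        sets["SET_PLANTED"] = GeneSet(
            "SET_PLANTED", "SET_PLANTED", "pathway",
            frozenset(g.upper() for g in planted_genes),
        )
    for i in range(n_sets):
        size = int(rng.integers(set_size[0], set_size[1] + 1))
        members = rng.choice(genes, size=min(size, len(genes)), replace=False)
        sid = f"SET{i + 1:04d}"
        sets[sid] = GeneSet(sid, sid, _ENRICH_CATEGORIES[i % 4], frozenset(members))
    return sets


@dataclass
class SimulatedStudy:
    """Everything one synthetic study produces, in memory."""

    config: SimulationConfig
    applications: pd.DataFrame
    addresses: pd.DataFrame
    covariates: pd.DataFrame      # includes op_count after exposure scoring
    profiles: pd.DataFrame        # participant x chemical window averages
    counts: pd.DataFrame          # copper_count / op_count
    beta: pd.DataFrame
    annotation: pd.DataFrame
    truth: GroundTruth


def simulate_study(config: SimulationConfig, radius_m: float = 500.0) -> SimulatedStudy:
    """Run the full generative chain: applications -> cohort -> buffer
    exposures -> window averages -> control-median counts -> beta matrix."""
    applications = generate_applications(config)
    addresses, covariates = generate_cohort(config)
    annual = exposure_mod.annual_buffer_exposure(
        applications, addresses, radius_m=radius_m,
        participants=covariates.index,
    )
    profiles = exposure_mod.average_window(
        annual, covariates["blood_draw_year"],
        chemicals=list(config.copper_codes) + list(config.op_codes),
    )
    controls = covariates.index[covariates["pd_status"] == 0]
    scores = exposure_mod.dichotomize_and_count(
        profiles, controls, config.copper_codes, config.op_codes
    )
    covariates = covariates.copy()
    covariates["op_count"] = scores.counts["op_count"]
    beta, annot, truth = generate_beta_matrix(config, scores.counts, covariates)
    return SimulatedStudy(
        config=config,
        applications=applications,
        addresses=addresses,
        covariates=covariates,
        profiles=profiles,
        counts=scores.counts,
        beta=beta,
        annotation=annot,
        truth=truth,
    )
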