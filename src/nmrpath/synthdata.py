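"""Synthetic serum-like 1H NMR spectra and toy pathway files with known truth.

The generator emulates the structure of a staged carcinogenesis study:
five groups with unbalanced sizes (control 32, then 11/15/15/11 across the
four pathological stages), ~20-40 metabolites rendered as Lorentzian
multiplets on a descending delta 9.00-0.00 ppm axis at 0.001-ppm resolution,
log-normal concentrations with latent-factor-induced inter-metabolite
correlations, group-dependent multiplicative mean shifts, a zeroed
residual-water region, per-sample peak-position jitter and additive
Gaussian noise. Pathway topologies are written as KGML-style XML so the
network stage can be exercised without any database download.

Everything is deterministic for a fixed seed: all randomness flows through
named ``numpy`` substreams spawned from the design seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

from .errors import ArgumentError, DesignError
from .preprocess import AssignmentMap, SpectrumMatrix

__all__ = [
    "SPECTRAL_WINDOW",
    "Peak",
    "MetaboliteSignature",
    "LatentFactor",
    "SimulationDesign",
    "SyntheticTruth",
    "make_metabolite_library",
    "simulate_concentrations",
    "render_spectra",
    "factor_model_correlation",
    "PathwayTopology",
    "make_toy_kgml",
    "random_pathway_topologies",
    "default_library",
    "default_design",
]

#: Usable spectral window in ppm (low edge, high edge).
SPECTRAL_WINDOW = (0.0, 9.0)
DEFAULT_RESOLUTION = 0.001
DEFAULT_HALFWIDTH = 0.002
DEFAULT_JITTER_SD = 0.002


@dataclass(frozen=True)
class Peak:
    center: float  # ppm
    amplitude: float  # relative, unitless, >= 0
    halfwidth: float  # Lorentzian half-width at half-maximum, ppm


@dataclass
class MetaboliteSignature:
    """A metabolite's multiplet pattern: a list of Lorentzian peaks."""

    name: str
    peaks: list[Peak]
    kegg_id: str | None = None

    def __post_init__(self) -> None:
        if not self.peaks:
            raise DesignError(f"signature '{self.name}' has no peaks")
        lo, hi = SPECTRAL_WINDOW
        for p in self.peaks:
            if not (lo < p.center < hi):
                raise DesignError(f"peak center {p.center} of '{self.name}' outside the window")
            if p.halfwidth <= 0 or p.amplitude < 0:
                raise DesignError(f"invalid peak geometry in '{self.name}'")
        if not (0 < sum(p.amplitude for p in self.peaks) < math.inf):
            raise DesignError(f"amplitudes of '{self.name}' must sum to a positive finite value")

    def windows(self, k: float = 6.0) -> list[tuple[float, float]]:
        """Per-peak ppm windows [center - k*hw, center + k*hw], clipped to the axis."""
        lo, hi = SPECTRAL_WINDOW
        return [
            (max(lo, p.center - k * p.halfwidth), min(hi, p.center + k * p.halfwidth))
            for p in self.peaks
        ]


@dataclass
class LatentFactor:
    """A common-cause factor on log-concentrations.

    ``loadings`` maps member metabolite names to loadings in [-1, 1]; the
    factor score is N(0, sd^2) per sample and enters each member's
    log-concentration multiplied by its loading.
    """

    loadings: dict[str, float]
    sd: float = 1.0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise DesignError("factor sd must be positive")
        for m, l in self.loadings.items():
            if not -1.0 <= l <= 1.0:
                raise DesignError(f"loading {l} of '{m}' outside [-1, 1]")


@dataclass
class SimulationDesign:
    """Study design: group sizes, per-group effects, correlation structure, noise.

    ``effect_matrix[metabolite][group]`` is a multiplicative mean shift
    (> 0) acting on the log-mean; 1.0 means unchanged. ``residual_sd`` is
    the per-metabolite residual sd of log-concentration (a scalar default
    with optional per-metabolite overrides).
    """

    group_sizes: dict[str, int]
    effect_matrix: dict[str, dict[str, float]] = field(default_factory=dict)
    latent_factors: list[LatentFactor] = field(default_factory=list)
    noise_sd: float = 0.005
    jitter_sd: float = DEFAULT_JITTER_SD
    residual_sd: float = 0.2
    residual_sd_overrides: dict[str, float] = field(default_factory=dict)
    base_log_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.group_sizes:
            raise DesignError("at least one group is required")
        for g, n in self.group_sizes.items():
            if n < 3:
                raise DesignError(f"group '{g}' has {n} samples; at least 3 required")
        for met, shifts in self.effect_matrix.items():
            for g, s in shifts.items():
                if s <= 0:
                    raise DesignError(f"effect {s} for '{met}' in '{g}' must be > 0")
        if self.noise_sd < 0 or self.jitter_sd < 0 or self.residual_sd < 0:
            raise DesignError("noise, jitter and residual sds must be non-negative")

    @property
    def n_samples(self) -> int:
        return sum(self.group_sizes.values())

    def residual_for(self, met: str) -> float:
        return self.residual_sd_overrides.get(met, self.residual_sd)


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a simulated data set."""

    concentrations: pd.DataFrame  # samples x metabolites
    group_labels: list[str]
    true_correlations: dict[tuple[str, str], float]  # realized Pearson of factor-mates
    true_differential: dict[str, dict[str, str]]  # metabolite -> group -> up/down/unchanged
    assignment_map: AssignmentMap
    perturbed_pathways: list[str] = field(default_factory=list)


def make_metabolite_library(
    n_metabolites: int,
    seed: int,
    max_peaks: int = 3,
    halfwidth: float = DEFAULT_HALFWIDTH,
    disjoint: bool = False,
    margin: float = 0.2,
) -> list[MetaboliteSignature]:
    """Random metabolite signatures with 1..max_peaks Lorentzian peaks each.

    With ``disjoint=True`` the usable window is partitioned into one slot per
    metabolite and all of a metabolite's peaks stay inside its own slot, so
    pairwise peak windows never intersect.
    """
    if n_metabolites < 2:
        raise ArgumentError("n_metabolites must be >= 2")
    rng = np.random.default_rng(seed)
    lo, hi = SPECTRAL_WINDOW
    lo, hi = lo + margin, hi - margin
    span = hi - lo
    min_footprint = 14 * halfwidth  # slot must hold a peak plus its window
    if disjoint and span / n_metabolites < min_footprint:
        raise DesignError(
            f"window too small to place {n_metabolites} disjoint signatures"
        )
    sigs: list[MetaboliteSignature] = []
    for i in range(n_metabolites):
        k = int(rng.integers(1, max_peaks + 1))
        if disjoint:
            slot_lo = lo + span * i / n_metabolites
            slot_hi = lo + span * (i + 1) / n_metabolites
            pad = 7 * halfwidth
            centers = rng.uniform(slot_lo + pad, slot_hi - pad, size=k)
        else:
            centers = rng.uniform(lo, hi, size=k)
        amps = rng.uniform(0.3, 1.0, size=k)
        amps = amps / amps.sum()
        peaks = [Peak(float(c), float(a), halfwidth) for c, a in sorted(zip(centers, amps))]
        sigs.append(MetaboliteSignature(name=f"met{i + 1:02d}", peaks=peaks))
    return sigs


def factor_model_correlation(
    l1: float, l2: float, factor_sd: float, r1: float, r2: float
) -> float:
    """Closed-form log-scale correlation of two metabolites sharing one factor."""
    s2 = factor_sd**2
    num = l1 * l2 * s2
    den = math.sqrt((l1**2 * s2 + r1**2) * (l2**2 * s2 + r2**2))
    return num / den


def _assignment_map_from_library(
    library: list[MetaboliteSignature], k: float = 6.0
) -> AssignmentMap:
    """Per-peak windows; a window is flagged overlapping when it intersects
    another metabolite's window. A metabolite's own touching windows are
    merged first (multiplet peaks can sit closer than the window width)."""

    def _merge(ws: list[tuple[float, float]]) -> list[tuple[float, float]]:
        merged: list[list[float]] = []
        for lo, hi in sorted(ws):
            if merged and lo <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        return [(lo, hi) for lo, hi in merged]

    wins = {s.name: _merge(s.windows(k)) for s in library}
    overlap: dict[str, list[bool]] = {}
    for s in library:
        flags = []
        for lo, hi in wins[s.name]:
            hit = any(
                o.name != s.name and lo <= ohi and olo <= hi
                for o in library
                for olo, ohi in wins[o.name]
            )
            flags.append(hit)
        overlap[s.name] = flags
    return AssignmentMap(windows=wins, overlapping=overlap)


def simulate_concentrations(
    design: SimulationDesign, library: list[MetaboliteSignature]
) -> SyntheticTruth:
    """Draw log-normal concentrations under the factor model.

    log c[s, m] = base_m + log(effect[m][group(s)]) + sum_f loading_f,m * z_f,s * sd_f
                  + eps with eps ~ N(0, residual_sd_m^2).
    """
    names = [s.name for s in library]
    name_set = set(names)
    for met in design.effect_matrix:
        if met not in name_set:
            raise DesignError(f"effect_matrix metabolite '{met}' not in library")
    for f in design.latent_factors:
        for met in f.loadings:
            if met not in name_set:
                raise DesignError(f"factor member '{met}' not in library")
    ss = np.random.SeedSequence(design.seed)
    r_base, r_factor, r_resid = [np.random.default_rng(s) for s in ss.spawn(3)]
    n = design.n_samples
    groups: list[str] = []
    for g, cnt in design.group_sizes.items():
        groups.extend([g] * cnt)
    base = r_base.normal(0.0, design.base_log_sd, size=len(names))
    logc = np.tile(base, (n, 1))
    for j, met in enumerate(names):
        shifts = design.effect_matrix.get(met, {})
        for i, g in enumerate(groups):
            s = shifts.get(g, 1.0)
            if s != 1.0:
                logc[i, j] += math.log(s)
    for f in design.latent_factors:
        z = r_factor.normal(0.0, f.sd, size=n)
        for met, loading in f.loadings.items():
            logc[:, names.index(met)] += loading * z
    for j, met in enumerate(names):
        logc[:, j] += r_resid.normal(0.0, design.residual_for(met), size=n)
    conc = np.exp(logc)
    sample_ids = [f"{g}_{i:03d}" for i, g in enumerate(groups)]
    frame = pd.DataFrame(conc, index=sample_ids, columns=names)

    # realized correlations of factor-mate pairs on the concentration scale
    true_corr: dict[tuple[str, str], float] = {}
    for f in design.latent_factors:
        members = sorted(f.loadings)
        for a_idx in range(len(members)):
            for b_idx in range(a_idx + 1, len(members)):
                a, b = members[a_idx], members[b_idx]
                r = float(np.corrcoef(frame[a], frame[b])[0, 1])
                true_corr[(a, b)] = r

    control = next(iter(design.group_sizes))
    diff: dict[str, dict[str, str]] = {}
    for met in names:
        shifts = design.effect_matrix.get(met, {})
        per_group = {}
        for g in design.group_sizes:
            if g == control:
                continue
            s = shifts.get(g, 1.0)
            per_group[g] = "up" if s > 1.0 else ("down" if s < 1.0 else "unchanged")
        diff[met] = per_group
    return SyntheticTruth(
        concentrations=frame,
        group_labels=groups,
        true_correlations=true_corr,
        true_differential=diff,
        assignment_map=_assignment_map_from_library(library),
    )


def _lorentzian(ppm: np.ndarray, center: float, hw: float) -> np.ndarray:
    return hw**2 / ((ppm - center) ** 2 + hw**2)


def render_spectra(
    truth: SyntheticTruth,
    library: list[MetaboliteSignature],
    design: SimulationDesign,
    lo: float = SPECTRAL_WINDOW[0],
    hi: float = SPECTRAL_WINDOW[1],
    resolution: float = DEFAULT_RESOLUTION,
    background: list[MetaboliteSignature] | None = None,
    background_scale: float = 0.0,
    eval_width: float = 0.12,
) -> SpectrumMatrix:
    """Render concentrations into bucketed spectra on a descending ppm axis.

    Bucket intensity = sum over metabolites of concentration x Lorentzian
    multiplet evaluated at the (jittered) bucket center, plus Gaussian noise.
    ``background`` signatures are unassigned extra signals (scaled to
    ``background_scale`` of a unit concentration each) so that cluster
    coverage is nontrivially below 100% on realistic settings. Peaks are
    evaluated on a +-``eval_width`` ppm neighbourhood, wide relative to the
    default 0.002-ppm halfwidth.
    """
    if resolution <= 0:
        raise ArgumentError("axis resolution must be > 0")
    nb = int(round((hi - lo) / resolution))
    axis = hi - resolution * (np.arange(nb) + 0.5)  # descending bucket centers
    conc = truth.concentrations
    n = conc.shape[0]
    ss = np.random.SeedSequence([design.seed, 7_654_321])
    r_jit, r_noise, r_bg = [np.random.default_rng(s) for s in ss.spawn(3)]
    out = np.zeros((n, nb))

    def _add(sig: MetaboliteSignature, amounts: np.ndarray) -> None:
        jit = r_jit.normal(0.0, design.jitter_sd, size=n) if design.jitter_sd > 0 else np.zeros(n)
        for p in sig.peaks:
            centers = p.center + jit
            sel = np.abs(axis - p.center) <= eval_width + 6 * design.jitter_sd
            if not sel.any():
                continue
            shape = _lorentzian(axis[None, sel], centers[:, None], p.halfwidth)
            out[:, sel] += (amounts * p.amplitude)[:, None] * shape

    for sig in library:
        _add(sig, conc[sig.name].to_numpy())
    for sig in background or []:
        amounts = background_scale * r_bg.lognormal(0.0, 0.2, size=n)
        _add(sig, amounts)
    if design.noise_sd > 0:
        out += r_noise.normal(0.0, design.noise_sd, size=out.shape)
    return SpectrumMatrix(
        sample_ids=list(conc.index),
        group_labels=list(truth.group_labels),
        ppm=axis,
        intensities=out,
        provenance=[{"op": "render_spectra", "seed": design.seed, "resolution": resolution}],
    )


# ---------------------------------------------------------------------------
# toy pathway (KGML-dialect) generation
# ---------------------------------------------------------------------------


@dataclass
class PathwayTopology:
    """Declarative pathway topology: compounds, enzymes and their incidences."""

    pathway_id: str
    name: str
    compounds: list[str]
    enzymes: list[str]
    links: list[tuple[str, str]]  # (compound, enzyme)

    def __post_init__(self) -> None:
        dup = set(self.compounds) & set(self.enzymes)
        if dup:
            raise DesignError(f"ids used as both compound and enzyme: {sorted(dup)}")
        known_c, known_e = set(self.compounds), set(self.enzymes)
        for c, e in self.links:
            if c not in known_c or e not in known_e:
                raise DesignError(f"link ({c}, {e}) references an undeclared node")


def make_toy_kgml(topologies: list[PathwayTopology], out_dir) -> list[Path]:
    """Write one KGML-dialect XML file per pathway.

    Entries are typed compound/enzyme; each enzyme carries one reaction whose
    substrates/products are the compounds it is linked to. Shared compounds
    across pathways keep identical identifiers so a later merge unifies them.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for topo in topologies:
        root = etree.Element(
            "pathway",
            name=f"path:{topo.pathway_id}",
            number=topo.pathway_id,
            title=topo.name,
        )
        ids: dict[str, str] = {}
        next_id = 1
        for c in topo.compounds:
            ids[c] = str(next_id)
            etree.SubElement(root, "entry", id=ids[c], name=f"cpd:{c}", type="compound")
            next_id += 1
        for e in topo.enzymes:
            ids[e] = str(next_id)
            etree.SubElement(
                root,
                "entry",
                id=ids[e],
                name=f"ec:{e}",
                type="enzyme",
                reaction=f"rn:R_{topo.pathway_id}_{e}",
            )
            next_id += 1
        by_enzyme: dict[str, list[str]] = {e: [] for e in topo.enzymes}
        for c, e in topo.links:
            by_enzyme[e].append(c)
        for e, comps in by_enzyme.items():
            if not comps:
                continue
            rx = etree.SubElement(
                root,
                "reaction",
                id=ids[e],
                name=f"rn:R_{topo.pathway_id}_{e}",
                type="reversible",
            )
            half = max(1, len(comps) // 2)
            for c in comps[:half]:
                etree.SubElement(rx, "substrate", id=ids[c], name=f"cpd:{c}")
            for c in comps[half:]:
                etree.SubElement(rx, "product", id=ids[c], name=f"cpd:{c}")
        path = out_dir / f"{topo.pathway_id}.xml"
        path.write_bytes(
            etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")
        )
        paths.append(path)
    return paths


def toy_pathways_for_library(
    metabolite_names: list[str],
    n_pathways: int = 5,
    seed: int = 0,
    shared: int = 1,
) -> list[PathwayTopology]:
    """Chain pathways over measured metabolites with invisible intermediates.

    Each pathway chains a slice of the measured metabolites, interleaving
    one unmeasured intermediate compound between consecutive measured ones
    (measured-measured graph distance 4: m - enzyme - intermediate -
    enzyme - m). The first ``shared`` metabolites of each slice are also
    appended to the previous pathway so consecutive pathways share
    compounds, as real pathway maps do.
    """
    if n_pathways < 1 or len(metabolite_names) < 2 * n_pathways:
        raise DesignError("need at least two metabolites per pathway")
    slices = [list(s) for s in np.array_split(np.array(metabolite_names), n_pathways)]
    topos: list[PathwayTopology] = []
    serial = 0
    for p, mets in enumerate(slices):
        mets = [str(m) for m in mets]
        if shared and p + 1 < len(slices):
            mets = mets + [str(m) for m in slices[p + 1][:shared]]
        compounds: list[str] = []
        enzymes: list[str] = []
        links: list[tuple[str, str]] = []
        prev: str | None = None
        for m in mets:
            if prev is not None:
                serial += 1
                inter = f"X{serial:04d}"
                e1, e2 = f"E{p + 1:02d}.{len(enzymes) + 1}", f"E{p + 1:02d}.{len(enzymes) + 2}"
                enzymes += [e1, e2]
                compounds.append(inter)
                links += [(prev, e1), (inter, e1), (inter, e2), (m, e2)]
            compounds.append(m)
            prev = m
        topos.append(
            PathwayTopology(
                pathway_id=f"tw{p + 1:05d}",
                name=f"toy pathway {p + 1}",
                compounds=compounds,
                enzymes=enzymes,
                links=links,
            )
        )
    return topos


def random_pathway_topologies(
    n_pathways: int,
    seed: int,
    n_compounds: tuple[int, int] = (4, 8),
    n_enzymes: tuple[int, int] = (3, 6),
    share_prob: float = 0.15,
) -> list[PathwayTopology]:
    """Random small pathway topologies with occasional shared compounds."""
    rng = np.random.default_rng(seed)
    topos: list[PathwayTopology] = []
    global_compounds: list[str] = []
    serial = 0
    for p in range(n_pathways):
        nc = int(rng.integers(n_compounds[0], n_compounds[1] + 1))
        ne = int(rng.integers(n_enzymes[0], n_enzymes[1] + 1))
        compounds: list[str] = []
        for _ in range(nc):
            if global_compounds and rng.random() < share_prob:
                pick = global_compounds[int(rng.integers(len(global_compounds)))]
                if pick not in compounds:
                    compounds.append(pick)
                    continue
            serial += 1
            cid = f"C{serial:05d}"
            compounds.append(cid)
            global_compounds.append(cid)
        enzymes = [f"E{p + 1:03d}.{k + 1}" for k in range(ne)]
        links: set[tuple[str, str]] = set()
        # chain through compounds so each pathway is connected
        for k in range(len(compounds) - 1):
            e = enzymes[k % ne]
            links.add((compounds[k], e))
            links.add((compounds[k + 1], e))
        extra = int(rng.integers(0, nc))
        for _ in range(extra):
            links.add(
                (
                    compounds[int(rng.integers(nc))],
                    enzymes[int(rng.integers(ne))],
                )
            )
        topos.append(
            PathwayTopology(
                pathway_id=f"tw{p + 1:05d}",
                name=f"toy pathway {p + 1}",
                compounds=compounds,
                enzymes=enzymes,
                links=sorted(links),
            )
        )
    return topos


# ---------------------------------------------------------------------------
# study-condition defaults
# ---------------------------------------------------------------------------

#: Group sizes of the staged design the generator emulates.
STUDY_GROUP_SIZES = {"CON": 32, "GS": 11, "LGD": 15, "HGD": 15, "GC": 11}


def default_library(seed: int = 0, n_metabolites: int = 30) -> list[MetaboliteSignature]:
    """The default ~30-metabolite library on the 9-0 ppm window."""
    return make_metabolite_library(n_metabolites, seed=seed, max_peaks=3)


def default_design(seed: int = 0, library: list[MetaboliteSignature] | None = None) -> SimulationDesign:
    """Five unbalanced groups with stage-graded effects and two latent factors.

    A subset of metabolites carries monotone up/down multiplicative shifts
    that strengthen along the stage sequence (emulating progressive
    metabolic drift), and two latent factors plant strong inter-metabolite
    correlations.
    """
    library = library or default_library(seed)
    names = [s.name for s in library]
    stages = ["GS", "LGD", "HGD", "GC"]
    up = names[0:4]
    down = names[4:8]
    effects: dict[str, dict[str, float]] = {}
    for met in up:
        effects[met] = {g: 1.0 + 0.25 * (k + 1) for k, g in enumerate(stages)}
    for met in down:
        effects[met] = {g: 1.0 / (1.0 + 0.2 * (k + 1)) for k, g in enumerate(stages)}
    factors = [
        LatentFactor(loadings={names[8]: 1.0, names[9]: 1.0}, sd=0.35),
        LatentFactor(loadings={names[10]: 1.0, names[11]: -1.0}, sd=0.35),
    ]
    overrides = {m: 0.05 for f in factors for m in f.loadings}
    return SimulationDesign(
        group_sizes=dict(STUDY_GROUP_SIZES),
        effect_matrix=effects,
        latent_factors=factors,
        residual_sd=0.2,
        residual_sd_overrides=overrides,
        noise_sd=0.005,
        jitter_sd=DEFAULT_JITTER_SD,
        seed=seed,
    )
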