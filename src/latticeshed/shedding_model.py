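"""Calibrated ctDNA fragment model and blood VAF sampling.

Cell death sheds DNA fragments into the plasma; at steady state the mean
number of circulating tumor fragments is C = N*d*q/eps (+ r, with the tumor
growth term r taken as 0 since fragment decay, eps = 48 ln 2 per day for a
30-minute half-life, is far faster than tumor growth).  The shedding
probability per cell death, q, is calibrated so that a tumor of
``n_at_detection`` cells dying at ``d_at_detection`` accounts for the
clinically observed 1% tumor fraction of cell-free DNA: with 29 ng/mL plasma
DNA and a 0.0033 ng haploid genome there are 8788 haploid genome equivalents
(HGE) per mL, hence C = 5000 mL * 0.55 * 8788 * 0.01 = 241,670 tumor
fragments in circulation at detection.

A 15 mL blood draw is 0.3% of the 5 L supply, so all fragment means are
thinned by ``draw_fraction`` = 0.003.  For a mutation m with tissue
frequency f_m and carrier mean death rate d_bar_m, the draw contains
Pois(f_m * N * d_bar_m * q / eps * 0.003) mutant fragments; assuming diploid
cells with the mutation on one copy, its blood VAF is

    VAF = Pois(Cm / 2) / Pois(Ct + Ch)

with Ct the tumor fragment mean (tumor-wide mean death rate d_bar) and Ch
the healthy fragment mean, held constant at 99% of the total fragments at
detection.  The spatially *biased* VAF uses d_bar_m; the *unbiased* null
replaces it with d_bar, so clonal mutations (f_m = 1) are identical under
both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .clone_ledger import RegionCounts, mutation_summary_from_clone_stats
from .scale_convert import ScaleParams, voxels_to_3d_population

__all__ = [
    "SheddingCalibration",
    "BloodSample",
    "calibrate_hge",
    "decay_rate",
    "calibrate_shedding_rate",
    "blood_clone_fractions",
    "fragment_means",
    "mutation_fragment_mean",
    "healthy_fragment_mean",
    "total_fragments_at_detection_mean",
    "sample_vaf",
    "draw_blood_sample",
    "vaf_time_series",
    "calibration_for",
]


def calibrate_hge(plasma_conc_ng_ml: float, genome_mass_ng: float) -> int:
    """Haploid genome equivalents per mL plasma (nearest integer)."""
    if plasma_conc_ng_ml <= 0 or genome_mass_ng <= 0:
        raise ValueError("plasma concentration and genome mass must be positive")
    return round(plasma_conc_ng_ml / genome_mass_ng)


def decay_rate(half_life_hours: float) -> float:
    """Exponential fragment decay rate per day from a half-life in hours."""
    if half_life_hours <= 0:
        raise ValueError("half-life must be positive")
    return (24.0 / half_life_hours) * math.log(2.0)


@dataclass(frozen=True)
class SheddingCalibration:
    """Constants of the ctDNA calibration chain (all overridable).

    ``ctot0_hge_per_ml`` deliberately keeps the rounded constant 8800 used
    for the total-fragment mean at detection, while the tumor-fragment chain
    uses the exact 8788 = round(29/0.0033); the two differ by ~0.1%.
    """

    plasma_conc_ng_ml: float = 29.0
    genome_mass_ng: float = 0.0033
    blood_volume_ml: float = 5000.0
    plasma_fraction: float = 0.55
    tumor_fraction_at_detection: float = 0.01
    half_life_hours: float = 0.5
    draw_fraction: float = 0.003  # 15 mL of 5 L
    growth_rate_r: float = 0.0
    n_at_detection: float = 3e9
    d_at_detection: float = 0.1
    ctot0_hge_per_ml: float = 8800.0

    @property
    def hge_per_ml(self) -> int:
        return calibrate_hge(self.plasma_conc_ng_ml, self.genome_mass_ng)

    @property
    def epsilon(self) -> float:
        """Fragment decay rate per day (48 ln 2 ~ 33.3 at a 30 min half-life)."""
        return decay_rate(self.half_life_hours)

    @property
    def tumor_fragments_at_detection(self) -> float:
        """C: circulating tumor fragments at the point of detection."""
        return (
            self.blood_volume_ml
            * self.plasma_fraction
            * self.hge_per_ml
            * self.tumor_fraction_at_detection
        )

    @property
    def q(self) -> float:
        return calibrate_shedding_rate(self)


def calibrate_shedding_rate(cal: SheddingCalibration) -> float:
    """Shedding probability per cell death, q = C*eps / (N_detect * d_detect).

    Solves C = N*d*q/eps at the detection anchor (r assumed 0).  Full
    precision is kept; at the defaults q = 0.0268.
    """
    if cal.n_at_detection <= 0 or cal.d_at_detection <= 0:
        raise ValueError("detection anchor N and d must be positive")
    return (
        cal.tumor_fragments_at_detection
        * cal.epsilon
        / (cal.n_at_detection * cal.d_at_detection)
    )


def blood_clone_fractions(rc: RegionCounts) -> pd.Series:
    """Clone fractions in ctDNA: death-rate-weighted region counts.

    fraction_i = sum_j d_j N_ij / sum_ij d_j N_ij.  Identical to the tissue
    fractions whenever d_core = d_edge.
    """
    if rc.total == 0:
        raise ValueError("empty tumor: no occupied voxels")
    weighted = rc.d_core * rc.counts["core"] + rc.d_edge * rc.counts["edge"]
    mass = weighted.sum()
    if mass <= 0:
        raise ValueError(
            "no shedding mass: all death-rate-weighted counts are zero "
            "(tumor occupied but nothing dies)"
        )
    return weighted / mass


def fragment_means(n_cells: float, d_bar: float, cal: SheddingCalibration) -> float:
    """Mean tumor fragments Ct in one blood draw: N*q*d_bar/eps * draw_fraction."""
    if n_cells < 0:
        raise ValueError("cell count must be non-negative")
    return n_cells * cal.q * d_bar / cal.epsilon * cal.draw_fraction


def mutation_fragment_mean(
    f_m: float, n_cells: float, d_bar_m: float, cal: SheddingCalibration
) -> float:
    """Mean mutant fragments Cm in one draw: f_m*N*d_bar_m*q/eps * draw_fraction.

    Pass the mutation's carrier mean death rate for the spatially biased
    model, or the tumor-wide mean death rate for the unbiased null.
    """
    if not 0.0 <= f_m <= 1.0:
        raise ValueError("tissue frequency must lie in [0, 1]")
    return f_m * n_cells * d_bar_m * cal.q / cal.epsilon * cal.draw_fraction


def total_fragments_at_detection_mean(cal: SheddingCalibration) -> float:
    """Mean total fragments Ctot0 in a draw at detection (rounded-HGE chain)."""
    return (
        cal.blood_volume_ml
        * cal.plasma_fraction
        * cal.ctot0_hge_per_ml
        * cal.draw_fraction
    )


def healthy_fragment_mean(cal: SheddingCalibration) -> float:
    """Mean healthy fragments Ch, held constant at (1 - tumor fraction)*Ctot0."""
    return (1.0 - cal.tumor_fraction_at_detection) * total_fragments_at_detection_mean(cal)


def sample_vaf(
    cm_mean: float,
    ct_mean: float,
    ch_mean: float,
    rng: np.random.Generator,
) -> float:
    """One VAF draw: Pois(cm/2) / Pois(ct + ch); NaN on a zero denominator.

    The numerator is Poisson(Cm/2) — half the mutant fragments carry the
    variant allele under diploidy — drawn independently of the denominator.
    A draw that recovers zero fragments total detects nothing and is
    reported as missing.
    """
    if min(cm_mean, ct_mean, ch_mean) < 0:
        raise ValueError("fragment means must be non-negative")
    num = rng.poisson(0.5 * cm_mean)
    den = rng.poisson(ct_mean + ch_mean)
    if den == 0:
        return float("nan")
    return num / den


@dataclass
class BloodSample:
    """One simulated 15 mL blood draw.

    ``vaf_table`` has one row per driver mutation with columns mutation_id,
    f_m, d_bar_m, cm_biased_mean, cm_unbiased_mean, vaf_biased, vaf_unbiased.
    """

    ct_mean: float
    ch_mean: float
    ctot0_mean: float
    denominator_draw: int
    vaf_table: pd.DataFrame


def draw_blood_sample(
    mut_table: pd.DataFrame,
    n_cells: float,
    d_bar: float,
    cal: SheddingCalibration,
    rng: np.random.Generator,
) -> BloodSample:
    """Sample biased and unbiased VAFs for every mutation in one blood draw.

    ``mut_table`` is a mutation census with columns f_m and d_bar_m.  The
    denominator (total fragments in the draw) is a single Poisson draw shared
    by all mutations of the sample; numerators are independent per mutation,
    except that a mutation whose biased and unbiased means coincide (clonal
    mutations) keeps one draw for both models.
    """
    ct = fragment_means(n_cells, d_bar, cal)
    ch = healthy_fragment_mean(cal)
    den = int(rng.poisson(ct + ch))
    f = mut_table["f_m"].to_numpy(dtype=float)
    dbm = mut_table["d_bar_m"].to_numpy(dtype=float)
    cm_biased = f * n_cells * np.nan_to_num(dbm) * cal.q / cal.epsilon * cal.draw_fraction
    cm_unbiased = f * n_cells * d_bar * cal.q / cal.epsilon * cal.draw_fraction
    num_biased = rng.poisson(0.5 * cm_biased)
    num_unbiased = rng.poisson(0.5 * cm_unbiased)
    # clonal mutations (identical means) cannot differ between the two
    # models: the unbiased draw is the same fragment count, not a new one
    same = cm_biased == cm_unbiased
    num_unbiased = np.where(same, num_biased, num_unbiased)
    if den == 0:
        vaf_biased = np.full(len(f), np.nan)
        vaf_unbiased = np.full(len(f), np.nan)
    else:
        vaf_biased = num_biased / den
        vaf_unbiased = num_unbiased / den
    table = pd.DataFrame(
        {
            "mutation_id": mut_table["mutation_id"].to_numpy(),
            "f_m": f,
            "d_bar_m": dbm,
            "cm_biased_mean": cm_biased,
            "cm_unbiased_mean": cm_unbiased,
            "vaf_biased": vaf_biased,
            "vaf_unbiased": vaf_unbiased,
        }
    )
    return BloodSample(
        ct_mean=ct,
        ch_mean=ch,
        ctot0_mean=total_fragments_at_detection_mean(cal),
        denominator_draw=den,
        vaf_table=table,
    )


def calibration_for(params, scale: ScaleParams = ScaleParams(), **overrides) -> SheddingCalibration:
    """Calibration anchored at a run's own detection size.

    Rescales ``n_at_detection`` to the 3D-equivalent population of the run's
    detection threshold and anchors ``d_at_detection`` at d1, so the 1%
    tumor fraction holds at detection for any (desk-scale) detection radius.
    """
    from .lattice_engine import detection_threshold

    n_det = voxels_to_3d_population(detection_threshold(params), scale)
    base = SheddingCalibration(n_at_detection=n_det, d_at_detection=params.d1)
    return replace(base, **overrides) if overrides else base


def vaf_time_series(
    traj,
    cal: SheddingCalibration,
    rng: np.random.Generator,
    scale: ScaleParams = ScaleParams(),
) -> pd.DataFrame:
    """Blood VAFs for every driver mutation at every recorded sweep.

    Returns a long table with the BloodSample columns plus ``sweep``.  The
    3D-equivalent population and tumor-wide mean death rate are recomputed
    per record; pre-detection records use d1 everywhere.
    """
    from .lattice_engine import Trajectory  # noqa: F401  (type of traj)

    frames = []
    for rec in traj.records:
        if rec.occupied_count == 0:
            continue
        d_edge = traj.params.d2 if rec.detected else traj.params.d1
        mut = mutation_summary_from_clone_stats(
            traj.ledger,
            rec.clone_ids,
            rec.core_counts,
            rec.edge_counts,
            rec.dist_sums,
            traj.params.d1,
            d_edge,
        )
        if mut.empty:
            continue
        n_cells = voxels_to_3d_population(rec.occupied_count, scale)
        core_tot = int(rec.core_counts.sum())
        edge_tot = int(rec.edge_counts.sum())
        d_bar = (traj.params.d1 * core_tot + d_edge * edge_tot) / rec.occupied_count
        sample = draw_blood_sample(mut, n_cells, d_bar, cal, rng)
        tab = sample.vaf_table.copy()
        tab.insert(0, "sweep", rec.sweep)
        frames.append(tab)
    if not frames:
        return pd.DataFrame(
            columns=[
                "sweep", "mutation_id", "f_m", "d_bar_m",
                "cm_biased_mean", "cm_unbiased_mean", "vaf_biased", "vaf_unbiased",
            ]
        )
    return pd.concat(frames, ignore_index=True)
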