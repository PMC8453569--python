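"""Canned simulation studies: parameter recovery, null calibration, power.

These are the package's own validation experiments, run at desk scale (a few
hundred animals, a few thousand SNPs) so each completes in minutes on one
CPU.  They use the same public pipeline a user would run, with known truth
from the generator.

Study designs (fixed, not tuning knobs):

* **recovery** - 300 animals x 10 chromosomes x 300 SNPs, 3 parities with 3-4
  test-days each (~3,000 records), true variance proportions
  (0.11, 0.07, 0.06, 0.40, 0.36) of a unit phenotypic variance - the fat-
  percentage-like structure - estimated by the null-model REML fit.
* **null calibration** - 120 animals x 4 chromosomes x 650 SNPs, 2 parities x
  4-5 test-days (~1,000 records), no regional effect anywhere; a ~100-window
  scan (50-SNP windows shifted by 25) per replicate tests the boundary
  mixture null distribution of the window LRT.
* **power/localization** - 400 animals x (400 + 300) SNPs on two chromosomes,
  2 parities x 3-4 test-days (~2,800 records), one QTL window spanning SNPs
  100-200 of chromosome 1 with regional variance 0.05 x sigma2_p; the scan
  uses the standard 100/50 windowing and the hit criterion is the max-LRT
  window sharing at least 50 QTL SNPs with the truth.

The recovery study uses the half-sib default (relatedness is what separates
the additive term from the across-lactation permanent environment); the
calibration and power studies use the unrelated generator mode, the clean
Hardy-Weinberg reference condition for the LRT's distributional properties,
and apply the standard genotype QC before scanning as the pipeline requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grm import build_grm
from .model import build_model_frame, fit_reml
from .qc import apply_genotype_qc
from .scan import ScanConfig, run_scan, scan_thresholds
from .simulate import SimulationConfig, simulate_dataset

#: variance proportions used by the recovery study (sum 1.0)
RECOVERY_TRUTH = {"u": 0.11, "pu": 0.07, "pw": 0.06, "h": 0.40, "e": 0.36}


def _child_seed(seed: int, rep: int, stream: int) -> int:
    """Deterministic sub-seed below 2^31."""
    return int(
        np.random.SeedSequence(seed, spawn_key=(stream, rep)).generate_state(1)[0]
        % (2**31 - 1)
    )


@dataclass
class RecoveryStudy:
    """Replicate REML fits on data simulated with known variance components."""

    n_replicates: int = 20
    seed: int = 1
    truth: dict[str, float] = field(default_factory=lambda: dict(RECOVERY_TRUTH))

    def run(self) -> dict:
        estimates: dict[str, list[float]] = {k: [] for k in self.truth}
        for rep in range(self.n_replicates):
            cfg = SimulationConfig(
                n_animals=300,
                snps_per_chromosome=[300] * 10,
                true_components=dict(self.truth),
                parities_per_animal=3,
                testdays_per_lactation=(3, 4),
                seed=_child_seed(self.seed, rep, 0),
            )
            ds, _, tab = simulate_dataset(cfg)
            frame = build_model_frame(tab, cfg.trait, {"u": build_grm(ds)})
            fit = fit_reml(frame)
            for k in self.truth:
                estimates[k].append(fit.components.as_dict()[k])
        out = {"truth": dict(self.truth), "estimates": estimates}
        out["mean"] = {k: float(np.mean(v)) for k, v in estimates.items()}
        # empirical SE of the mean over replicates
        out["se_mean"] = {
            k: float(np.std(v, ddof=1) / np.sqrt(len(v))) for k, v in estimates.items()
        }
        out["z"] = {
            k: (out["mean"][k] - self.truth[k]) / out["se_mean"][k] for k in self.truth
        }
        return out


@dataclass
class NullCalibrationStudy:
    """Distribution of window LRTs when no regional variance exists anywhere."""

    n_replicates: int = 50
    seed: int = 2

    def run(self) -> dict:
        from scipy.stats import chi2

        all_lrts: list[np.ndarray] = []
        sug_counts: list[int] = []
        n_windows = None
        sug_lrt = None
        for rep in range(self.n_replicates):
            cfg = SimulationConfig(
                n_animals=120,
                snps_per_chromosome=[650] * 4,
                n_sire_families=0,
                parities_per_animal=2,
                testdays_per_lactation=(4, 5),
                seed=_child_seed(self.seed, rep, 1),
            )
            ds, _, tab = simulate_dataset(cfg)
            ds, _ = apply_genotype_qc(ds)
            res = run_scan(
                ds, tab, cfg.trait, config=ScanConfig(window_size=50, shift=25, min_tail=25)
            )
            lrts = np.array([r.lrt for r in res])
            all_lrts.append(lrts)
            n_windows = len(res)
            sug_lrt = res.thresholds.suggestive_lrt
            sug_counts.append(int((lrts > sug_lrt).sum()))
        lrts = np.concatenate(all_lrts)
        # mixture quantile at alpha: LRT q with 0.5 * Pr(chi2_1 >= q) = alpha
        out = {
            "n_windows": n_windows,
            "n_replicates": self.n_replicates,
            "n_tests": int(lrts.size),
            "frac_zero": float((lrts == 0.0).mean()),
            "suggestive_lrt": sug_lrt,
            "suggestive_counts": sug_counts,
            "mean_suggestive_per_scan": float(np.mean(sug_counts)),
        }
        for alpha in (0.05, 0.01):
            q = float(chi2.isf(2 * alpha, df=1))
            out[f"exceedance_{alpha}"] = float((lrts > q).mean())
            out[f"quantile_{alpha}"] = q
        return out


@dataclass
class PowerStudy:
    """Localization of a single QTL window across replicate scans."""

    n_replicates: int = 20
    seed: int = 3
    regional_share: float = 0.05  # sigma2_v as a fraction of sigma2_p
    min_shared_snps: int = 50

    def run(self) -> dict:
        hits = []
        max_lrts = []
        base = SimulationConfig()  # for the default component values
        sigma_p = base.total_variance()
        s2v = self.regional_share * sigma_p
        true_span = (100, 200)  # chromosome-1 SNP index range of the QTL
        for rep in range(self.n_replicates):
            cfg = SimulationConfig(
                n_animals=400,
                snps_per_chromosome=[400, 300],
                n_sire_families=0,
                parities_per_animal=2,
                testdays_per_lactation=(3, 4),
                qtl_windows=[("1", true_span, s2v)],
                seed=_child_seed(self.seed, rep, 2),
            )
            ds, _, tab = simulate_dataset(cfg)
            # QTL membership tracked by SNP id: QC below may shift indices
            truth_ids = set(
                ds.marker_map["snp_id"].iloc[
                    ds.snp_indices("1")[true_span[0] : true_span[1]]
                ]
            )
            ds, _ = apply_genotype_qc(ds)
            res = run_scan(ds, tab, cfg.trait)
            best = res.max_lrt()
            w = best.window
            window_ids = set(ds.marker_map["snp_id"].iloc[w.start : w.stop])
            shared = len(window_ids & truth_ids)
            hits.append(shared >= self.min_shared_snps)
            max_lrts.append(best.lrt)
        return {
            "n_replicates": self.n_replicates,
            "hits": int(sum(hits)),
            "hit_fraction": float(np.mean(hits)),
            "max_lrts": max_lrts,
            "sigma2_v": s2v,
        }
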