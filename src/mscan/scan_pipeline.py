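"""Run the full multi-test selection scan on one dataset.

Five test families — diversity summaries, Ewens-Watterson, the FDIST-style
frequentist outlier test, the hierarchical Bayesian F_ST test, pairwise
lnR statistics, and DetSel-style divergence envelopes — run from one
config with one master seed (per-module seeds derived by hashing), and the
per-locus results are merged into a consensus report: the tier of a locus
is the number of distinct test families flagging it, the working notion of
"supported by several methods".
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    bayesfst_outlier,
    detsel_pairwise,
    diversity_stats,
    ewens_watterson,
    fdist_outlier,
    genotype_io,
    lnr_pairwise,
)

logger = logging.getLogger("mscan")

__all__ = ["ScanConfig", "OutlierReport", "run_scan", "report_tables",
           "module_seed"]


def module_seed(master: int, module: str) -> int:
    """Stable per-module seed below 2^31 derived from the master seed."""
    return zlib.crc32(f"{master}:{module}".encode()) & 0x7FFFFFFF


@dataclass
class ScanConfig:
    genepop: str | None = None
    marker_map: str | None = None
    seed: int = 1
    tests: tuple[str, ...] = ("diversity", "ewens", "fdist", "bayesfst",
                              "lnr", "detsel")
    ewens_repeats: int = 20
    ewens_sims: int = 1000
    fdist_iterations: int = 50000
    fdist_demes: int = 100
    fdist_sample_size: int = 50
    fdist_trim: float = 0.30
    bayes_chains: int = 4
    bayes_iterations: int = 20000
    bayes_thin: int = 10
    lnr_pairs: str | list = "preset"
    lnr_candidate_loci: list | None = None
    lnr_theta_sims: int = 1500
    detsel_pairs: list | None = None
    detsel_sims: int = 10000
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScanConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class LocusReport:
    locus: str
    diversity: diversity_stats.DiversityRecord | None = None
    ewens: ewens_watterson.EwensResult | None = None
    fdist: fdist_outlier.FdistResult | None = None
    bayesfst: bayesfst_outlier.BayesFstResult | None = None
    lnr_flags: int = 0          # significant (pair, statistic) cells
    lnr_cells: int = 0
    detsel_flags: dict = field(default_factory=dict)
    consensus_tier: int = 0

    def flagged_by(self) -> list[str]:
        hits = []
        if self.ewens is not None and self.ewens.significant:
            hits.append("ewens")
        if self.fdist is not None and self.fdist.direction != "none":
            hits.append("fdist")
        if self.bayesfst is not None and self.bayesfst.direction != "none":
            hits.append("bayesfst")
        if self.lnr_flags > 0:
            hits.append("lnr")
        if any(v.get(0.95) for v in self.detsel_flags.values()):
            hits.append("detsel")
        return hits


@dataclass
class OutlierReport:
    loci: dict[str, LocusReport]
    multilocus_fst: diversity_stats.MultiLocusFst | None = None
    trimmed_mean_fst: float = float("nan")
    flag_table: lnr_pairwise.FlagTable | None = None
    errors: dict[str, str] = field(default_factory=dict)
    config: ScanConfig | None = None


def run_scan(
    config: ScanConfig | str | Path,
    ds: genotype_io.GenotypeDataset | None = None,
    mmap: genotype_io.MarkerMap | None = None,
) -> OutlierReport:
    """Execute the configured test battery and build the consensus report.

    ``ds``/``mmap`` may be passed directly (e.g. synthetic data); otherwise
    they are read from the paths in the config. Module failures are caught
    and recorded in ``report.errors`` so partial reports still emerge.
    """
    cfg = (config if isinstance(config, ScanConfig)
           else ScanConfig.from_yaml(config))
    if ds is None:
        if cfg.genepop is None:
            raise ValueError("no dataset: config lacks a genepop path")
        ds = genotype_io.read_genepop(cfg.genepop)
    if mmap is None and cfg.marker_map is not None:
        mmap = genotype_io.read_marker_map(cfg.marker_map)

    report = OutlierReport(
        loci={l: LocusReport(locus=l) for l in ds.loci}, config=cfg)

    if "diversity" in cfg.tests:
        try:
            recs, ml = diversity_stats.weir_cockerham(
                ds, rng=module_seed(cfg.seed, "diversity"))
            for r in recs:
                report.loci[r.locus].diversity = r
            report.multilocus_fst = ml
            report.trimmed_mean_fst = diversity_stats.trimmed_mean_fst(
                [r.F_ST for r in recs if np.isfinite(r.F_ST)],
                trim=cfg.fdist_trim)
        except Exception as e:  # noqa: BLE001 - partial reports by design
            logger.exception("diversity module failed")
            report.errors["diversity"] = str(e)

    if "ewens" in cfg.tests:
        rng = np.random.default_rng(module_seed(cfg.seed, "ewens"))
        for loc in ds.loci:
            try:
                tab = genotype_io.allele_counts(ds, loc)
                report.loci[loc].ewens = ewens_watterson.ew_test(
                    tab, rng=rng, n_repeats=cfg.ewens_repeats,
                    sims_per_repeat=cfg.ewens_sims)
            except ValueError:
                continue
            except Exception as e:  # noqa: BLE001
                logger.exception("ewens failed at %s", loc)
                report.errors[f"ewens:{loc}"] = str(e)

    if "fdist" in cfg.tests:
        try:
            results, null, trimmed = fdist_outlier.fdist_scan(
                ds, iterations=cfg.fdist_iterations, trim=cfg.fdist_trim,
                d=cfg.fdist_demes, sample_size=cfg.fdist_sample_size,
                seed=module_seed(cfg.seed, "fdist"))
            for r in results:
                report.loci[r.locus].fdist = r
            report.trimmed_mean_fst = trimmed
        except Exception as e:  # noqa: BLE001
            logger.exception("fdist module failed")
            report.errors["fdist"] = str(e)

    if "bayesfst" in cfg.tests:
        try:
            post = bayesfst_outlier.fit_bayesfst(
                ds, chains=cfg.bayes_chains, iterations=cfg.bayes_iterations,
                thin=cfg.bayes_thin, rng=module_seed(cfg.seed, "bayesfst"))
            for r in bayesfst_outlier.classify_outliers(post):
                report.loci[r.locus].bayesfst = r
        except Exception as e:  # noqa: BLE001
            logger.exception("bayesfst module failed")
            report.errors["bayesfst"] = str(e)

    pairs: list[tuple[str, str]] = []
    if "lnr" in cfg.tests:
        try:
            if cfg.lnr_pairs == "preset":
                pairs = lnr_pairwise.polled_horned_pairs(ds.populations)
            elif cfg.lnr_pairs == "all":
                import itertools
                pairs = list(itertools.combinations(ds.populations, 2))
            else:
                pairs = [tuple(p) for p in cfg.lnr_pairs]
            records, tbl = lnr_pairwise.lnr_scan(
                ds, pairs, candidate_loci=cfg.lnr_candidate_loci,
                rng=module_seed(cfg.seed, "lnr"),
                theta_sims=cfg.lnr_theta_sims)
            report.flag_table = tbl
            for rec in records:
                lr = report.loci[rec.locus]
                lr.lnr_cells += 1
                if rec.flag in ("*", "**"):
                    lr.lnr_flags += 1
        except Exception as e:  # noqa: BLE001
            logger.exception("lnr module failed")
            report.errors["lnr"] = str(e)

    if "detsel" in cfg.tests:
        try:
            dpairs = (cfg.detsel_pairs if cfg.detsel_pairs is not None
                      else pairs[:3])
            rng = np.random.default_rng(module_seed(cfg.seed, "detsel"))
            for (pa, pb) in [tuple(p) for p in dpairs]:
                na = 2 * ds.genotypes[ds.pop_index(pa)].shape[0]
                nb = 2 * ds.genotypes[ds.pop_index(pb)].shape[0]
                env = detsel_pairwise.simulate_envelope(
                    detsel_pairwise.NuisanceGrid(), sample_sizes=(na, nb),
                    sims=cfg.detsel_sims, rng=rng)
                obs = [detsel_pairwise.branch_lengths(ds, pa, pb, l)
                       for l in ds.loci]
                flags = detsel_pairwise.flag_outliers(
                    [b for b in obs if b is not None], env)
                for loc, f in flags.items():
                    report.loci[loc].detsel_flags[f"{pa}-{pb}"] = f
        except Exception as e:  # noqa: BLE001
            logger.exception("detsel module failed")
            report.errors["detsel"] = str(e)

    for lr in report.loci.values():
        lr.consensus_tier = len(lr.flagged_by())

    if cfg.out_dir is not None:
        write_artifacts(report, cfg.out_dir, mmap)
    return report


def report_tables(
    report: OutlierReport, mmap: genotype_io.MarkerMap | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(per-locus summary table, pairwise flag matrix) as DataFrames."""
    rows = []
    for loc, lr in report.loci.items():
        chrom = (mmap[loc].chromosome if mmap is not None and loc in mmap
                 else "NA")
        row = {"locus": loc, "BTA": chrom}
        d = lr.diversity
        row.update({
            "A_R": d.A_R if d else float("nan"),
            "H_E": d.H_E if d else float("nan"),
            "F_IS": d.F_IS if d else float("nan"),
            "F_ST": d.F_ST if d else float("nan"),
        })
        row.update({
            "fdist_P": lr.fdist.p_value if lr.fdist else float("nan"),
            "fdist_dir": lr.fdist.direction if lr.fdist else "",
            "F_OBS": lr.ewens.F_obs if lr.ewens else float("nan"),
            "F_EXP": lr.ewens.F_exp if lr.ewens else float("nan"),
            "P_H": lr.ewens.P_H if lr.ewens else float("nan"),
            "P_E": lr.ewens.P_E if lr.ewens else float("nan"),
            "bayes_dir": lr.bayesfst.direction if lr.bayesfst else "",
            "lnr_flags": lr.lnr_flags,
            "detsel_out95": sum(bool(v.get(0.95))
                                for v in lr.detsel_flags.values()),
            "consensus_tier": lr.consensus_tier,
            "flagged_by": ",".join(lr.flagged_by()),
        })
        rows.append(row)
    locus_table = pd.DataFrame(rows)
    flag_matrix = (report.flag_table.frame.copy()
                   if report.flag_table is not None
                   else pd.DataFrame(index=pd.Index([], name="pair")))
    return locus_table, flag_matrix


def write_artifacts(
    report: OutlierReport, out_dir: str | Path,
    mmap: genotype_io.MarkerMap | None = None,
) -> None:
    """Write the TSV/JSON artifacts of one scan into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t1, t2 = report_tables(report, mmap)
    t1.to_csv(out / "locus_summary.tsv", sep="\t", index=False,
              float_format="%.6g")
    t2.to_csv(out / "pairwise_flags.tsv", sep="\t")
    meta = {
        "multilocus_fst": (
            {"point": report.multilocus_fst.point,
             "ci": [report.multilocus_fst.ci_low,
                    report.multilocus_fst.ci_high]}
            if report.multilocus_fst else None),
        "trimmed_mean_fst": report.trimmed_mean_fst,
        "errors": report.errors,
        "seed": report.config.seed if report.config else None,
    }
    (out / "scan_meta.json").write_text(json.dumps(meta, indent=2))
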