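"""Ground-truth methylomes for the simulated cfDNA populations.

Each cfDNA population carries its own per-CpG-site methylation probability
over the nuclear reference.  Defaults reflect the biology the simulator
emulates: the ultrashort single-stranded population is globally less
methylated (~64%) than the mononucleosomal population (~80%); CpG islands
are hypomethylated in every population; annotated hypo-/hyper-methylated
regions override the baseline; the mitochondrial genome is essentially
unmethylated; the lambda spike-in is exactly unmethylated.  Non-CpG (CHG/
CHH) methylation is a single small probability, near zero as in somatic
tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeBundle

__all__ = ["MethylomeParams", "MethylomeTruth", "build_methylome"]

POPULATIONS = ("uscfDNA", "mncfDNA", "gDNA_HMW", "lambda")


@dataclass(frozen=True)
class MethylomeParams:
    """Population-level methylation means and regional overrides."""

    population_means: dict[str, float] = field(
        default_factory=lambda: {"uscfDNA": 0.64, "mncfDNA": 0.80, "gDNA_HMW": 0.80, "lambda": 0.0}
    )
    island_level: float | None = 0.10
    hypo_region_level: float | None = 0.05
    hyper_region_level: float | None = 0.95
    mito_level: float = 0.02
    chh_level: float = 0.002

    def __post_init__(self) -> None:
        for pop, v in self.population_means.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"methylation mean for {pop} out of [0,1]: {v}")


@dataclass
class MethylomeTruth:
    """Per-population, per-CpG-site methylation probabilities.

    ``sites[genome]`` holds the top-strand C positions of every CpG dyad;
    ``probs[(population, genome)]`` the matching probability vector.
    """

    sites: dict[str, np.ndarray]
    probs: dict[tuple[str, str], np.ndarray]
    chh_prob: float = 0.002

    def site_index(self, genome: str) -> dict[int, int]:
        return {int(p): i for i, p in enumerate(self.sites[genome])}

    def prob_vector(self, population: str, genome: str) -> np.ndarray:
        return self.probs[(population, genome)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (pop, genome), pv in sorted(self.probs.items()):
            sites = self.sites[genome]
            rows.append(
                pd.DataFrame(
                    {
                        "population": pop,
                        "chrom": genome,
                        "pos": sites,
                        "strand": "+",
                        "context": "CpG",
                        "truth_prob": pv,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def load(cls, path: str | Path, chh_prob: float = 0.002) -> "MethylomeTruth":
        df = pd.read_csv(path, sep="\t")
        sites: dict[str, np.ndarray] = {}
        probs: dict[tuple[str, str], np.ndarray] = {}
        for (pop, genome), sub in df.groupby(["population", "chrom"], sort=True):
            sub = sub.sort_values("pos")
            sites[genome] = sub["pos"].to_numpy()
            probs[(pop, genome)] = sub["truth_prob"].to_numpy(dtype=float)
        return cls(sites=sites, probs=probs, chh_prob=chh_prob)


def build_methylome(
    bundle: GenomeBundle, params: MethylomeParams | None = None, seed: int = 0
) -> MethylomeTruth:
    """Assign a methylation probability to every CpG site for every population.

    The baseline is the population mean; island / hypo-region / hyper-region
    overrides apply to nuclear sites inside the corresponding tracks (in that
    order of precedence, later overrides winning).  The lambda reference is
    identically 0 for every population; mito sites sit at ``mito_level``.
    """
    prm = params or MethylomeParams()
    sites = {g: bundle.cpg_sites(g) for g in bundle.references}
    probs: dict[tuple[str, str], np.ndarray] = {}

    nuc = sites.get("nuclear", np.array([], dtype=int))
    in_island = _sites_in_track(nuc, bundle, "cpg_island")
    in_hypo = _sites_in_track(nuc, bundle, "hypomethylated_region")
    in_hyper = _sites_in_track(nuc, bundle, "hypermethylated_region")

    for pop, mean in prm.population_means.items():
        for genome in bundle.references:
            n = len(sites[genome])
            if genome == "lambda" or pop == "lambda":
                pv = np.zeros(n)
            elif genome == "mito":
                pv = np.full(n, prm.mito_level)
            else:
                pv = np.full(n, mean)
                if prm.island_level is not None:
                    pv[in_island] = prm.island_level
                if prm.hypo_region_level is not None:
                    pv[in_hypo] = prm.hypo_region_level
                if prm.hyper_region_level is not None:
                    pv[in_hyper] = prm.hyper_region_level
            probs[(pop, genome)] = pv
    return MethylomeTruth(sites=sites, probs=probs, chh_prob=prm.chh_level)


def _sites_in_track(positions: np.ndarray, bundle: GenomeBundle, track: str) -> np.ndarray:
    """Boolean mask of positions falling inside any interval of a nuclear track."""
    mask = np.zeros(len(positions), dtype=bool)
    if track not in bundle.annotations:
        return mask
    for iv in bundle.annotations[track]:
        lo = np.searchsorted(positions, iv.start, side="left")
        hi = np.searchsorted(positions, iv.end, side="left")
        mask[lo:hi] = True
    return mask
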