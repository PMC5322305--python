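"""End-to-end orchestration of the metacommunity analysis.

For each gut site (metacommunity) the pipeline runs: core/satellite
partitioning -> Fisher's alpha diversity (whole/core/satellite, with sex
comparisons) -> Raup-Crick stochasticity classification -> burden-median
dysbiosis (volcano + gained/lost) -> CCA forward selection of host variables;
plus between-site ANOSIM and SIMPER. Every stage's result is exported as a TSV
with ``#``-prefixed header metadata (seed, parameters), and a JSON run log
records versions, seeds and parameters. The whole run is deterministic under a
fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from micrometa import io
from micrometa.cca import encode_variables, forward_select
from micrometa.comparison import anosim, bray_curtis_matrix, simper, to_relative
from micrometa.diversity import diversity_comparisons, diversity_table
from micrometa.dysbiosis import gained_lost, split_by_median, volcano
from micrometa.partition import partition_core_satellite
from micrometa.raupcrick import classify_assembly, raup_crick_matrix
from micrometa.simulate import GeneratorConfig, simulate_dataset

logger = logging.getLogger("micrometa")

FRACTIONS = ("whole", "core", "satellite")
HOST_VARIABLES = ("age_years", "sex", "nematode_count", "phenology")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    When ``counts_path`` is unset, a synthetic dataset is generated with
    :class:`~micrometa.simulate.GeneratorConfig` defaults at ``seed``.
    Round-trips losslessly through a flat key=value file.
    """

    counts_path: str | None = None
    metadata_path: str | None = None
    output_dir: str = "micrometa_out"
    site_column: str = "site"
    burden_column: str = "nematode_count"
    fractions: tuple = FRACTIONS
    tail: float = 0.025
    n_rand: int = 1000
    n_perm_anosim: int = 9999
    n_perm_cca: int = 1000
    alpha: float = 0.05
    seed: int = 0

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                v = getattr(self, f.name)
                if isinstance(v, tuple):
                    v = ",".join(v)
                fh.write(f"{f.name}={'' if v is None else v}\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        kv = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k, _, v = line.partition("=")
            kv[k.strip()] = v.strip()
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in kv:
                continue
            raw = kv[f.name]
            if raw == "":
                kwargs[f.name] = None
            elif f.name == "fractions":
                kwargs[f.name] = tuple(raw.split(","))
            elif f.type in ("int",):
                kwargs[f.name] = int(raw)
            elif f.type in ("float",):
                kwargs[f.name] = float(raw)
            else:
                kwargs[f.name] = raw
        return cls(**kwargs)


def _write(df: pd.DataFrame, path: Path, meta: dict, index=True) -> None:
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=index)


def _fraction_table(table, part, fraction):
    taxa = sorted(part.fraction_taxa(fraction) & set(table.index))
    return table.loc[taxa]


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns a nested dict of in-memory results.

    Outputs land in ``config.output_dir`` (created if needed). Samples lacking
    a burden value are excluded from the dysbiosis and burden-CCA stages with a
    logged warning but analysed everywhere else.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).generate_state(8) % (2**31)

    if config.counts_path:
        counts = io.read_count_table(config.counts_path)
        metadata = io.read_metadata(config.metadata_path)
        truth = None
    else:
        sim = simulate_dataset(GeneratorConfig(seed=int(seeds[0])))
        counts, metadata, truth = sim.counts, sim.sample_metadata, sim.truth
        io.write_count_table(counts, out / "counts.tsv", {"seed": config.seed})
        io.write_metadata(metadata, out / "sample_metadata.tsv", {"seed": config.seed})
    io.validate_inputs(counts, metadata)
    if config.site_column not in metadata.columns:
        raise ValueError(f"metadata lacks site column {config.site_column!r}")

    base_meta = {"seed": config.seed, "package": "micrometa"}
    results: dict = {"sites": {}, "between_sites": {}}
    sites = list(pd.unique(metadata[config.site_column]))

    for k, site in enumerate(sites):
        samples = metadata.index[metadata[config.site_column] == site]
        sub = counts[counts.columns.intersection(samples)]
        sub = sub.loc[sub.sum(axis=1) > 0]
        sr: dict = {}
        prefix = out / site.replace("/", "_")
        prefix.mkdir(exist_ok=True)

        # 1. partition
        part = partition_core_satellite(sub, tail=config.tail)
        sr["partition"] = part
        _write(part.taxa, prefix / "partition.tsv", {**base_meta, "tail": config.tail, "chi2_limit": part.chi2_limit})
        if part.regression is not None:
            _write(pd.DataFrame([part.regression]), prefix / "occupancy_abundance_regression.tsv", base_meta, index=False)

        # 2. diversity
        div = diversity_table(sub, part, fractions=config.fractions)
        sr["diversity"] = div
        _write(div, prefix / "diversity.tsv", base_meta, index=False)
        sex_cmp = diversity_comparisons(div, metadata, "sex")
        sr["diversity_by_sex"] = sex_cmp
        _write(sex_cmp, prefix / "diversity_by_sex.tsv", base_meta, index=False)

        # 3. Raup-Crick per fraction
        sr["raup_crick"] = {}
        for i, fraction in enumerate(config.fractions):
            ftab = _fraction_table(sub, part, fraction)
            src = raup_crick_matrix(ftab, n_rand=config.n_rand, seed=int(seeds[1]) + 100 * k + i)
            cls = classify_assembly(src)
            sr["raup_crick"][fraction] = cls
            _write(src, prefix / f"raup_crick_{fraction}.tsv", {**base_meta, "n_rand": config.n_rand})
            _write(cls.histogram, prefix / f"raup_crick_hist_{fraction}.tsv", {**base_meta, **cls.as_dict()}, index=False)

        # 4. burden dysbiosis
        burden = metadata.loc[sub.columns, config.burden_column]
        missing = burden.index[burden.isna()]
        if len(missing):
            logger.warning("%s: %d sample(s) lack burden values; excluded from dysbiosis", site, len(missing))
        split = split_by_median(burden.dropna())
        sr["burden_split"] = split
        volc = volcano(sub, split, part, alpha=config.alpha)
        gl = gained_lost(sub, split, part)
        sr["volcano"], sr["gained_lost"] = volc, gl
        _write(volc, prefix / "volcano.tsv", {**base_meta, "median_burden": split.median, "n_high": split.n_high, "n_low": split.n_low})
        _write(gl, prefix / "gained_lost.tsv", base_meta)

        # 5. CCA forward selection per fraction
        sr["cca"] = {}
        have_vars = [v for v in HOST_VARIABLES if v in metadata.columns]
        X = encode_variables(metadata.loc[sub.columns], have_vars).dropna()
        for i, fraction in enumerate(config.fractions):
            ftab = _fraction_table(sub, part, fraction)[X.index]
            ftab = ftab.loc[:, ftab.sum(axis=0) > 0]
            fs = forward_select(ftab, X.loc[ftab.columns], n_perm=config.n_perm_cca,
                                alpha=config.alpha, seed=int(seeds[2]) + 100 * k + i)
            sr["cca"][fraction] = fs
            _write(fs.selected, prefix / f"cca_forward_{fraction}.tsv",
                   {**base_meta, "total_inertia": fs.total_inertia,
                    "undetermined_pct": fs.undetermined_pct}, index=False)
        results["sites"][site] = sr

    # 6. between-site ANOSIM / SIMPER per fraction
    rel = to_relative(counts.loc[counts.sum(axis=1) > 0])
    site_of = metadata[config.site_column]
    anosim_rows = []
    for fraction in config.fractions:
        fr_taxa = set()
        for site in sites:
            fr_taxa |= results["sites"][site]["partition"].fraction_taxa(fraction)
        ftab = rel.loc[sorted(fr_taxa & set(rel.index))]
        for a_i in range(len(sites)):
            for b_i in range(a_i + 1, len(sites)):
                a, b = sites[a_i], sites[b_i]
                cols = [c for c in ftab.columns if site_of[c] in (a, b)]
                pair_tab = ftab[cols]
                keep = pair_tab.sum(axis=0) > 0
                pair_tab = pair_tab.loc[:, keep]
                dm = bray_curtis_matrix(pair_tab)
                groups = site_of[pair_tab.columns].to_numpy()
                res = anosim(dm, groups, n_perm=config.n_perm_anosim, seed=int(seeds[3]))
                anosim_rows.append({"fraction": fraction, "site_a": a, "site_b": b,
                                    "R": res.R, "P": res.p,
                                    "mean_between_bc": res.mean_between, "sd_between_bc": res.sd_between})
                if fraction == "whole":
                    sim = simper(pair_tab, groups, relative=False)
                    _write(sim, out / f"simper_{a}_vs_{b}.tsv",
                           {**base_meta, "overall_mean_dissimilarity": sim.attrs["overall_mean_dissimilarity"]})
                    results["between_sites"][f"simper_{a}_vs_{b}"] = sim
    anosim_df = pd.DataFrame(anosim_rows)
    results["between_sites"]["anosim"] = anosim_df
    _write(anosim_df, out / "anosim_between_sites.tsv", {**base_meta, "n_perm": config.n_perm_anosim}, index=False)

    if truth is not None:
        results["truth"] = truth

    log = {
        "package": "micrometa",
        "config": {f.name: getattr(config, f.name) if not isinstance(getattr(config, f.name), tuple)
                   else list(getattr(config, f.name)) for f in dataclasses.fields(config)},
        "derived_seeds": [int(s) for s in seeds],
        "sites": sites,
        "n_samples": int(counts.shape[1]),
        "n_taxa": int(counts.shape[0]),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    config.to_file(out / "run_config.txt")
    return results
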