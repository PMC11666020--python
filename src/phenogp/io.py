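"""File formats, run configuration, manifest and the end-to-end pipeline.

CSV schemas (all UTF-8, comma-delimited, '.' decimal; genotype ids are opaque
strings):

* genotype dosage matrix - first column ``genotype``, then one column per
  marker id, values 0/1/2 or empty;
* phenotypes (long) - genotype, year, nitro, rep, block, trait, value
  (an ``env`` column ``YYYY-HN``/``YYYY-LN`` is derived if absent);
* spectra (wide) - genotype, env, rep, block then ``wl_####`` columns;
* kinship - header row of ids, one row per id, plus a sidecar ``.json``
  provenance file.

VCF input is read with cyvcf2 (biallelic GT records; multiallelic sites are
skipped with a count); VCF output is minimal v4.2 with GT only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .crossval import make_scenarios, run_scenario, compare_models
from .kinship import Kinship, filter_snps, grm_vanraden, hrm
from .models import ChainParams
from .phenotypes import blues_all_environments
from .simulate import (
    GenotypeMatrix,
    SpectraSet,
    default_spectra_spec,
    default_trait_specs,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_spectra,
    simulate_trial_design,
)
from .spectra import preprocess, spectra_blups

__all__ = [
    "RunConfig",
    "RunManifest",
    "read_genotypes",
    "write_genotypes_csv",
    "write_genotypes_vcf",
    "read_phenotypes",
    "write_phenotypes",
    "read_spectra",
    "write_spectra",
    "read_kinship",
    "write_kinship",
    "run_pipeline",
]

log = logging.getLogger("phenogp")

PHENO_COLUMNS = ["genotype", "year", "nitro", "rep", "block", "trait", "value"]


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path, fmt: str | None = None) -> GenotypeMatrix:
    path = str(path)
    if fmt is None:
        fmt = "vcf" if path.endswith((".vcf", ".vcf.gz")) else "csv"
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "csv":
        df = pd.read_csv(path, index_col=0)
        return GenotypeMatrix(
            dosages=df.to_numpy(dtype=float),
            ids=[str(i) for i in df.index],
            marker_ids=[str(c) for c in df.columns],
        )
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    ids = list(vcf.samples)
    dosages, marker_ids, chrom, pos, ref, alt = [], [], [], [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gt = var.gt_types.astype(float)       # 0/1/2, 3 = unknown
        gt[gt == 3] = np.nan
        dosages.append(gt)
        marker_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chrom.append(var.CHROM)
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0])
    if n_multi:
        log.info("skipped %d multiallelic VCF records", n_multi)
    if not dosages:
        raise ValueError(f"no biallelic records in {path}")
    return GenotypeMatrix(
        dosages=np.column_stack(dosages),
        ids=ids,
        marker_ids=marker_ids,
        chrom=np.asarray(chrom),
        pos=np.asarray(pos),
        ref=np.asarray(ref),
        alt=np.asarray(alt),
    )


def write_genotypes_csv(geno: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(geno.dosages, index=pd.Index(geno.ids, name="genotype"),
                      columns=geno.marker_ids)
    df.to_csv(path, float_format="%.0f")


def write_genotypes_vcf(geno: GenotypeMatrix, path) -> None:
    """Minimal biallelic VCF v4.2 with GT only (0/0, 0/1, 1/1, ./.)."""
    code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.ids) + "\n")
        for j, mid in enumerate(geno.marker_ids):
            calls = [
                code.get(geno.dosages[i, j], "./.")
                if not np.isnan(geno.dosages[i, j]) else "./."
                for i in range(geno.n_individuals)
            ]
            fh.write(
                f"{geno.chrom[j]}\t{geno.pos[j]}\t{mid}\t{geno.ref[j]}\t{geno.alt[j]}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


# ---------------------------------------------------------------------------
# phenotypes & spectra
# ---------------------------------------------------------------------------

def read_phenotypes(path, environments: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file lacks columns: {missing}")
    if "env" not in df.columns:
        df["env"] = df["year"].astype(str) + "-" + df["nitro"].astype(str)
    if environments is not None:
        bad = sorted(set(df["env"]) - set(environments))
        if bad:
            raise ValueError(
                f"unknown environment labels {bad}; valid: {sorted(environments)}"
            )
    dup = df.duplicated(subset=["genotype", "env", "rep", "trait"])
    if dup.any():
        raise ValueError(f"{int(dup.sum())} duplicated (genotype, env, rep, trait) rows")
    return df


def write_phenotypes(records: pd.DataFrame, path) -> None:
    cols = [c for c in ["genotype", "year", "nitro", "env", "rep", "block", "trait", "value"]
            if c in records.columns]
    records[cols].to_csv(path, index=False)


def read_spectra(path, environments: list[str] | None = None) -> SpectraSet:
    df = pd.read_csv(path)
    wl_cols = [c for c in df.columns if c.startswith("wl_")]
    if not wl_cols:
        raise ValueError("spectra file has no wl_#### columns")
    grid = np.array([float(c[3:]) for c in wl_cols])
    steps = np.diff(np.sort(grid))
    if steps.size:
        med = np.median(steps)
        gaps = np.flatnonzero(steps > 1.6 * med)   # a dropped column, not rounding
        if gaps.size:
            missing = np.sort(grid)[gaps[0]] + med
            raise ValueError(f"spectra wavelength grid has gaps; missing wl_{int(round(missing))}")
    if environments is not None:
        bad = sorted(set(df["env"]) - set(environments))
        if bad:
            raise ValueError(f"unknown environment labels {bad}; valid: {sorted(environments)}")
    order = np.argsort(grid)
    return SpectraSet(
        data=df[[c for c in df.columns if not c.startswith("wl_")]
                + [wl_cols[i] for i in order]],
        wavelength_grid=grid[order],
    )


def write_spectra(spectra: SpectraSet, path) -> None:
    spectra.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# kinships
# ---------------------------------------------------------------------------

def read_kinship(path) -> Kinship:
    df = pd.read_csv(path, index_col=0)
    prov_path = Path(str(path) + ".json")
    prov = json.loads(prov_path.read_text()) if prov_path.exists() else {}
    return Kinship(
        matrix=df.to_numpy(dtype=float),
        ids=[str(i) for i in df.index],
        kind=prov.get("kind", "genomic"),
        provenance=prov.get("provenance", {}),
    )


def write_kinship(kin: Kinship, path) -> None:
    kin.dataframe().to_csv(path)
    Path(str(path) + ".json").write_text(
        json.dumps({"kind": kin.kind, "provenance": kin.provenance}, indent=2)
    )


# ---------------------------------------------------------------------------
# configuration, manifest, pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end run settings; synthetic data is generated when no input paths
    are given."""

    out_dir: str = "results"
    seed: int = 1
    # synthetic-data sizes (used when genotype/phenotype/spectra paths are None)
    n_genotypes: int = 50
    n_markers: int = 500
    n_wavelengths: int = 100
    n_blocks: int = 5
    traits: list = field(default_factory=lambda: ["GY"])
    genotypes_path: str | None = None
    phenotypes_path: str | None = None
    spectra_path: str | None = None
    preprocessing: str = "der2"
    sg_window: int = 37
    chain_preset: str = "fast"
    scenarios: list = field(default_factory=lambda: [1, 5])
    models: list = field(default_factory=lambda: ["MDs"])
    infos: list = field(default_factory=lambda: ["GP", "PP"])
    n_replicates: int = 2
    max_het: float = 1.0          # binomial synthetic genotypes are outbred-style
    convert_het: bool = False
    min_maf: float = 0.025
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def validate(self) -> None:
        valid = {s.scenario_id for s in make_scenarios(["a", "b", "c", "d"])}
        bad = [s for s in self.scenarios if s not in valid]
        if bad:
            raise ValueError(f"unknown scenario ids {bad}; valid 1-14")
        for p in (self.genotypes_path, self.phenotypes_path, self.spectra_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    def chain(self, seed: int = 0) -> ChainParams:
        return ChainParams.paper(seed) if self.chain_preset == "paper" else ChainParams.fast(seed)


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    stages: dict = field(default_factory=dict)   # stage -> {outputs: {path: sha256}, seconds}
    started: str = ""
    finished: str = ""

    def write(self, path) -> None:
        # atomic write so a crash never leaves a half manifest
        tmp = str(path) + ".tmp"
        Path(tmp).write_text(json.dumps(dataclasses.asdict(self), indent=2))
        os.replace(tmp, path)


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> RunManifest:
    """Simulate (or load) data, compute BLUEs, spectral BLUPs, kinships, run the
    requested scenarios and write the full results tree under ``out_dir``.

    Stages whose outputs already exist with checksums recorded in a previous
    manifest for an identical configuration are skipped (resumable runs).
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = dataclasses.asdict(config)
    manifest = RunManifest(config=cfg_dict, version=__version__, seed=config.seed,
                           started=time.strftime("%Y-%m-%dT%H:%M:%S"))
    prev = None
    man_path = out / "manifest.json"
    if man_path.exists():
        try:
            prev = json.loads(man_path.read_text())
            if prev.get("config") != cfg_dict:
                prev = None
        except (json.JSONDecodeError, OSError):
            prev = None

    def stage_done(name, outputs):
        if prev is None or name not in prev.get("stages", {}):
            return False
        rec = prev["stages"][name]["outputs"]
        return all(Path(p).exists() and _sha256(p) == rec.get(str(p)) for p in outputs)

    def record(name, outputs, t0):
        manifest.stages[name] = {
            "outputs": {str(p): _sha256(p) for p in outputs},
            "seconds": round(time.time() - t0, 2),
        }

    # --- stage: data -------------------------------------------------------
    t0 = time.time()
    geno_csv = out / "genotypes.csv"
    pheno_csv = out / "phenotypes.csv"
    spectra_csv = out / "spectra.csv"
    data_files = [geno_csv, pheno_csv, spectra_csv]
    if config.genotypes_path:
        geno = read_genotypes(config.genotypes_path)
        records = read_phenotypes(config.phenotypes_path)
        spectra = read_spectra(config.spectra_path)
        design = None
        if stage_done("data", []):
            log.info("stage data: external inputs")
        record("data", [], t0)
    else:
        environments = [(2015, "HN"), (2015, "LN"), (2016, "HN"), (2016, "LN")]
        trait_specs = default_trait_specs(environments)
        if stage_done("data", data_files):
            log.info("stage data: outputs up to date, skipping")
            geno = read_genotypes(geno_csv, fmt="csv")
            records = read_phenotypes(pheno_csv)
            spectra = read_spectra(spectra_csv)
            manifest.stages["data"] = prev["stages"]["data"]
        else:
            geno = simulate_genotypes(config.n_genotypes, config.n_markers, seed=config.seed)
            design = simulate_trial_design(config.n_genotypes, n_blocks=config.n_blocks,
                                           seed=config.seed)
            parts = []
            truths = {}
            for t in config.traits:
                rec, truth = simulate_phenotypes(geno, design, trait_specs[t], seed=config.seed)
                parts.append(rec)
                truths[t] = truth["genetic_values"]
            records = pd.concat(parts, ignore_index=True)
            spectra, _ = simulate_spectra(
                geno, design, default_spectra_spec(config.n_wavelengths), seed=config.seed
            )
            write_genotypes_csv(geno, geno_csv)
            write_phenotypes(records, pheno_csv)
            write_spectra(spectra, spectra_csv)
            pd.DataFrame(truths).to_csv(out / "truth_genetic_values.csv")
            record("data", data_files, t0)

    env_labels = sorted(records["env"].unique())

    # --- stage: blues ------------------------------------------------------
    t0 = time.time()
    blues_csv = out / "blues.csv"
    if stage_done("blues", [blues_csv]):
        blues = pd.read_csv(blues_csv)
        manifest.stages["blues"] = prev["stages"]["blues"]
    else:
        blues = pd.concat(
            [blues_all_environments(records, t) for t in config.traits], ignore_index=True
        )
        blues.to_csv(blues_csv, index=False)
        record("blues", [blues_csv], t0)

    # --- stage: spectral BLUPs + kinships ----------------------------------
    t0 = time.time()
    kin_files = [out / "K.csv"] + [out / f"H_{e}.csv" for e in env_labels]
    if stage_done("kinships", kin_files):
        grm = read_kinship(out / "K.csv")
        hrms = {e: read_kinship(out / f"H_{e}.csv") for e in env_labels}
        manifest.stages["kinships"] = prev["stages"]["kinships"]
    else:
        filtered, report = filter_snps(geno, max_het=config.max_het,
                                       min_maf=config.min_maf,
                                       convert_het=config.convert_het)
        log.info("SNP filter: %d -> %d markers", report.n_input, report.n_retained)
        grm = grm_vanraden(filtered)
        write_kinship(grm, out / "K.csv")
        pre = preprocess(spectra, config.preprocessing, window=config.sg_window) \
            if config.preprocessing != "none" else spectra
        hrms = {}
        for e in env_labels:
            sb = spectra_blups(pre, e)
            sb.sp.to_csv(out / f"spblups_{e}.csv")
            pd.DataFrame({"wavelength": sb.wavelength_grid, "h2": sb.h2}).to_csv(
                out / f"wavelength_h2_{e}.csv", index=False
            )
            hrms[e] = hrm(sb)
            write_kinship(hrms[e], out / f"H_{e}.csv")
        record("kinships", kin_files, t0)

    # --- stage: cross-validation -------------------------------------------
    t0 = time.time()
    pa_csv = out / "pa.csv"
    if stage_done("cv", [pa_csv]):
        pa_all = pd.read_csv(pa_csv)
        manifest.stages["cv"] = prev["stages"]["cv"]
    else:
        specs = {s.scenario_id: s for s in make_scenarios(env_labels)}
        tables = []
        for t in config.traits:
            tb = blues[blues["trait"] == t]
            for sid in config.scenarios:
                spec = specs[sid]
                for model in config.models:
                    use_model = "SM" if spec.k_folds else model
                    for info in config.infos:
                        res = run_scenario(
                            spec, use_model, info, tb, grm=grm, hrms=hrms,
                            chain=config.chain(), n_replicates=config.n_replicates,
                            master_seed=config.seed,
                        )
                        tab = res.table.copy()
                        tab.insert(0, "trait", t)
                        tables.append(tab)
                        for row in tab.itertuples(index=False):
                            log.info("scenario %s %s/%s frac %s rep %d PA %.3f",
                                     sid, use_model, info, row.fraction,
                                     row.replicate, row.pa)
        pa_all = pd.concat(tables, ignore_index=True)
        pa_all.to_csv(pa_csv, index=False)
        summary = pa_all.groupby(["trait", "scenario", "model", "info", "fraction"])["pa"] \
            .agg(["mean", "std"]).reset_index()
        summary.to_csv(out / "pa_summary.csv", index=False)
        record("cv", [pa_csv], t0)

    # --- stage: comparison ---------------------------------------------------
    t0 = time.time()
    cmp_csv = out / "comparison.csv"
    pa_all = pd.read_csv(pa_csv)   # file-backed values so resumed runs agree
    factors = [f for f in ("info", "fraction", "model") if pa_all[f].nunique() > 1]
    if factors and pa_all["pa"].notna().sum() >= 4:
        cmp = compare_models(pa_all, factors)
        rows = []
        for f, tab in cmp["level_means"].items():
            for r in tab.itertuples(index=False):
                rows.append(dict(factor=f, level=getattr(r, f), pa_mean=r.pa_mean))
        pd.DataFrame(rows).to_csv(cmp_csv, index=False)
        record("comparison", [cmp_csv], t0)

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(man_path)
    return manifest
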