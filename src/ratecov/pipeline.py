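"""End-to-end runs: simulate -> RER -> ERC -> complex tests, and
simulate/load -> overlap enrichment, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, enrichment, erc, io, simulate

__all__ = ["RunManifest", "run_erc_pipeline", "run_enrichment_pipeline"]


@dataclass
class RunManifest:
    tool_version: str
    subcommand: str
    parameters: dict
    seed: int | None
    input_digests: dict[str, str]
    output_paths: list[str]
    output_digests: dict[str, str]
    wall_time_s: float

    def write(self, path: Path) -> None:
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")
        tmp.replace(path)  # atomic on POSIX


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _fresh_dir(outdir: str | Path) -> Path:
    out = Path(outdir)
    if out.exists() and any(out.iterdir()):
        raise FileExistsError(f"output directory {out} exists and is not empty")
    out.mkdir(parents=True, exist_ok=True)
    return out


def _tree_cfg_from_dict(d: dict, seed: int | None) -> simulate.TreeSimConfig:
    complexes = tuple(
        simulate.ComplexSpec(name=c["name"], members=tuple(c["members"]),
                             rho=float(c.get("rho", 0.8)))
        for c in d.get("complexes", ()))
    kwargs = {k: v for k, v in d.items() if k != "complexes"}
    if "gene_scale_range" in kwargs:
        kwargs["gene_scale_range"] = tuple(kwargs["gene_scale_range"])
    return simulate.TreeSimConfig(complexes=complexes, seed=seed, **kwargs)


def run_erc_pipeline(config: dict, outdir: str | Path) -> RunManifest:
    """simulate/load branch lengths -> RER -> ERC -> complex permutation tests.

    ``config`` keys: ``seed`` (required where randomness occurs); either
    ``simulate`` (TreeSimConfig fields + complexes) or ``inputs`` with
    ``matrix`` (TSV) and ``complexes`` (membership file); ``tests`` — list of
    {a, b} complex-name pairs; optional ``erc`` parameter block
    (winsor_k, min_branches, trim_frac, epsilon, r_clamp,
    min_genes_per_branch) and ``n_perm``.
    """
    t0 = time.monotonic()
    out = _fresh_dir(outdir)
    seed = config.get("seed")
    digests: dict[str, str] = {}

    if "simulate" in config:
        cfg = _tree_cfg_from_dict(dict(config["simulate"]), seed)
        tree = simulate.simulate_species_tree(cfg)
        blm = simulate.simulate_branch_lengths(tree, cfg)
        complexes = simulate.planted_complex_sets(cfg)
        io.write_species_tree(tree, out / "species.nwk")
        io.write_matrix_tsv(blm, out / "branch_lengths.tsv", seed=seed)
        io.write_complexes(complexes, out / "complexes.tsv")
    elif "inputs" in config:
        inputs = config["inputs"]
        for key in ("matrix", "complexes"):
            if key not in inputs:
                raise ValueError(f"config inputs missing {key!r}")
            if not Path(inputs[key]).exists():
                raise FileNotFoundError(inputs[key])
        blm = io.read_matrix_tsv(inputs["matrix"])
        complexes = io.read_complexes(inputs["complexes"])
        digests = {k: _digest(v) for k, v in inputs.items()}
    else:
        raise ValueError("config needs a 'simulate' or 'inputs' block")

    tests = config.get("tests")
    if not tests:
        raise ValueError("config needs >= 1 complex pair under 'tests'")
    by_name = {c.name: c for c in complexes}
    # extra named gene sets (by gene id, or by index into a simulated matrix)
    for s in config.get("sets", ()):
        members = tuple(
            blm.genes[i] if isinstance(i, int) else str(i)
            for i in s["members"])
        by_name[s["name"]] = io.ComplexSet(s["name"], members)
    for t in tests:
        for key in ("a", "b"):
            if t[key] not in by_name:
                raise ValueError(f"unknown complex {t[key]!r} in tests")

    p = config.get("erc", {})
    model = erc.fit_rer_model(
        blm, trim_frac=p.get("trim_frac", erc.DEFAULT_TRIM_FRAC),
        min_genes_per_branch=p.get("min_genes_per_branch",
                                   erc.DEFAULT_MIN_GENES_PER_BRANCH),
        epsilon=p.get("epsilon", erc.DEFAULT_EPSILON))
    rer = erc.compute_rer(blm, model)
    matrix = erc.erc_matrix(
        rer, k=p.get("winsor_k", erc.DEFAULT_WINSOR_K),
        min_branches=p.get("min_branches", erc.DEFAULT_MIN_BRANCHES),
        r_clamp=p.get("r_clamp", erc.DEFAULT_R_CLAMP))

    io.write_results_tsv(erc.pairs_table(matrix), out / "pairs.tsv", seed=seed)

    n_perm = int(config.get("n_perm", 1000))
    rows, long_rows = [], []
    for t in tests:
        a, b = by_name[t["a"]], by_name[t["b"]]
        res = erc.complex_permutation_test(matrix, a, b,
                                           n_perm=n_perm, seed=seed)
        rows.append({
            "complex_a": res.complex_a, "complex_b": res.complex_b,
            "n_pairs": res.n_pairs, "observed": res.observed_stat,
            "null_mean": res.null_mean, "null_sd": res.null_sd,
            "p_empirical": res.p_empirical, "n_perm": res.n_permutations,
            "seed": res.seed})
        for (x, y), v in erc.between_set_values(matrix, a, b):
            long_rows.append({"complex_a": a.name, "complex_b": b.name,
                              "gene_a": x, "gene_b": y, "erc": v})
    io.write_results_tsv(pd.DataFrame(rows), out / "complex_tests.tsv",
                         seed=seed)
    io.write_results_tsv(pd.DataFrame(long_rows),
                         out / "between_values_long.tsv", seed=seed)

    outputs = sorted(str(q.relative_to(out)) for q in out.iterdir())
    manifest = RunManifest(
        tool_version=__version__, subcommand="pipeline-erc",
        parameters=config, seed=seed, input_digests=digests,
        output_paths=outputs,
        output_digests={q: _digest(out / q) for q in outputs},
        wall_time_s=round(time.monotonic() - t0, 3))
    manifest.write(out / "manifest.json")
    return manifest


def run_enrichment_pipeline(config: dict, outdir: str | Path) -> RunManifest:
    """simulate/load genome + features + peaks -> overlap permutation test.

    ``config`` keys: ``seed``; either ``simulate`` (GenomeSimConfig fields) or
    ``inputs`` with ``query`` (BED), ``subject`` (BED or GFF3 +
    ``feature_types``), ``genome`` (chrom.sizes); optional ``n_perm``
    (default 10000), ``alternative``, ``mode``.
    """
    t0 = time.monotonic()
    out = _fresh_dir(outdir)
    seed = config.get("seed")
    digests: dict[str, str] = {}

    if "simulate" in config:
        cfg = simulate.GenomeSimConfig(seed=seed, **{
            k: (tuple(v) if k == "chrom_lengths" and not isinstance(v, int)
                else v)
            for k, v in config["simulate"].items()})
        genome, subject, query = simulate.simulate_genome_with_peaks(cfg)
        io.write_genome_table(genome, out / "chrom.sizes")
        io.write_bed(subject, out / "features.bed", seed=seed)
        io.write_bed(query, out / "peaks.bed", seed=seed)
    elif "inputs" in config:
        inputs = config["inputs"]
        for key in ("query", "subject", "genome"):
            if key not in inputs:
                raise ValueError(f"config inputs missing {key!r}")
            if not Path(inputs[key]).exists():
                raise FileNotFoundError(inputs[key])
        query = io.read_bed(inputs["query"])
        subj_path = str(inputs["subject"])
        if subj_path.endswith((".gff", ".gff3")):
            subject = io.read_gff3_features(
                subj_path, inputs.get("feature_types", ["ARS"]))
        else:
            subject = io.read_bed(subj_path)
        genome = io.read_genome_table(inputs["genome"])
        digests = {k: _digest(v) for k, v in inputs.items()}
    else:
        raise ValueError("config needs a 'simulate' or 'inputs' block")

    n_perm = int(config.get("n_perm", 10000))
    res = enrichment.overlap_permutation_test(
        query, subject, genome, n_perm=n_perm, seed=seed,
        alternative=config.get("alternative", "enrichment"),
        mode=config.get("mode", "uniform"))
    ov = enrichment.count_overlapping(query, subject)
    io.write_results_tsv(pd.DataFrame([{
        "observed": res.observed, "n_query": ov.n_query,
        "percent": ov.percent, "null_mean": res.null_mean,
        "null_sd": res.null_sd, "z": res.z,
        "p_empirical": res.p_empirical, "p_normal": res.p_normal,
        "n_perm": res.n_permutations, "seed": res.seed,
    }]), out / "enrichment.tsv", seed=seed)

    # null-count histogram (the bar-distribution data shape)
    rng = np.random.default_rng(seed)
    null = np.array([
        enrichment.count_overlapping(
            enrichment.shuffle_intervals(query, genome, rng,
                                         mode=config.get("mode", "uniform")),
            subject).n_overlapping
        for _ in range(min(n_perm, 2000))])
    counts = pd.Series(null).value_counts().sort_index()
    io.write_results_tsv(
        pd.DataFrame({"n_overlapping": counts.index, "count": counts.values}),
        out / "null_histogram.tsv", seed=seed)

    outputs = sorted(str(q.relative_to(out)) for q in out.iterdir())
    manifest = RunManifest(
        tool_version=__version__, subcommand="pipeline-enrich",
        parameters=config, seed=seed, input_digests=digests,
        output_paths=outputs,
        output_digests={q: _digest(out / q) for q in outputs},
        wall_time_s=round(time.monotonic() - t0, 3))
    manifest.write(out / "manifest.json")
    return manifest
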