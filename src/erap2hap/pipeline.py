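"""One-command reproduction pipeline: HWE -> association -> LD -> blocks ->
compound-genotype analysis -> epistasis, with TSV/JSON reports and a run log.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .block_detection import (
    blocks_confidence_interval,
    blocks_four_gamete,
    blocks_solid_spine,
)
from .compound_genotype import (
    compound_table,
    expected_counts,
    observed_vs_expected_test,
    predict_expression,
)
from .epistasis_glm import interaction_test
from .genotype_model import (
    CohortLabels,
    GenotypeTable,
    allele_frequency,
    genotype_counts,
    read_genotypes,
)
from .haplotype_em import em_haplotype_freqs, ld_matrix
from .popgen_stats import (
    allelic_association,
    bonferroni,
    genotypic_association,
    hwe_test,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

GENO_LABELS = ("2", "1", "0")  # index-allele copies, descending


@dataclass
class RunConfig:
    genotypes: str
    output_dir: str
    phenotypes: str | None = None
    format: str | None = None
    stratum: str | None = None
    snp_pair: tuple[str, str] = ("rs2248374", "rs2549782")
    index_allele_a: str | None = None  # defaults: minor of snp_a
    index_allele_b: str | None = None
    expectation_mode: str = "naive_product"
    fidelity_round: bool = True  # round allele freqs to 2 dp as published
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0,1)")


class PipelineError(RuntimeError):
    """An analysis stage failed; the message names the stage."""


def _stage(name: str):
    def wrap(fn):
        def run(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name}: {exc}") from exc

        return run

    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write a report bundle to output_dir.

    Returns a summary dict (also written as ``summary.json``).  All text
    outputs use fixed decimal formatting so repeated runs diff cleanly.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": {k: str(v) for k, v in vars(config).items()}}

    table, labels = _load(config)
    if config.stratum and labels is not None:
        chosen = [s for s in labels.in_stratum(config.stratum) if s in set(table.samples)]
        if not chosen:
            raise PipelineError(
                f"stage load: no samples in stratum {config.stratum!r}"
            )
        table = table.subset(chosen)

    summary["n_samples"] = table.n_samples
    summary["snps"] = table.snp_ids

    _run_hwe(table, out, summary)
    if labels is not None:
        _run_association(table, labels, config, out, summary)
    mat = _run_ld(table, config, out, summary)
    _run_blocks(table, config, out, summary)
    _run_compound(table, labels, config, out, summary)
    if labels is not None:
        _run_epistasis(table, labels, config, out, summary)

    summary["versions"] = {
        "erap2hap": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    with open(out / "run.log", "w") as fh:
        fh.write(f"erap2hap {__version__} pipeline run\n")
        fh.write(f"seed: {config.seed}\n")
        for key in ("n_samples", "snps"):
            fh.write(f"{key}: {summary[key]}\n")
    return summary


@_stage("load")
def _load(config: RunConfig) -> tuple[GenotypeTable, CohortLabels | None]:
    table = read_genotypes(config.genotypes, format=config.format)
    labels = None
    if config.phenotypes is not None:
        labels = CohortLabels.from_csv(config.phenotypes)
        labels.validate_against(table)
    return table, labels


@_stage("hwe")
def _run_hwe(table: GenotypeTable, out: Path, summary: dict) -> None:
    rows = []
    for snp in table.snp_ids:
        counts = genotype_counts(table, snp)
        res = hwe_test(counts)
        rows.append(
            f"{snp}\t{allele_frequency(counts):.3f}\t{res.method}\t"
            f"{res.statistic:.3f}\t{res.p_value:.3e}"
        )
    (out / "hwe.tsv").write_text(
        "snp\tmaf\tmethod\tstatistic\tp\n" + "\n".join(rows) + "\n"
    )
    summary["hwe"] = {r.split("\t")[0]: float(r.split("\t")[4]) for r in rows}


@_stage("association")
def _run_association(
    table: GenotypeTable,
    labels: CohortLabels,
    config: RunConfig,
    out: Path,
    summary: dict,
) -> None:
    case_ids = [s for s in labels.cases() if s in set(table.samples)]
    ctrl_ids = [s for s in labels.controls() if s in set(table.samples)]
    rows, pvals = [], []
    for snp in table.snp_ids:
        case = genotype_counts(table, snp, case_ids)
        ctrl = genotype_counts(table, snp, ctrl_ids)
        allelic = allelic_association(case, ctrl)
        geno = genotypic_association(case, ctrl)
        pvals.append(allelic.test.p_value)
        rows.append(
            f"{snp}\tallelic\t{allelic.odds_ratio:.3f}\t{allelic.test.p_value:.3e}\t"
            f"genotypic\t{geno.statistic:.3f}\t{geno.p_value:.3e}"
        )
    corr = bonferroni(pvals, config.alpha)
    body = [
        row + f"\t{pc:.3e}" for row, pc in zip(rows, corr.p_corrected)
    ]
    (out / "association.tsv").write_text(
        "snp\ttest\tOR\tp\ttest2\tchisq\tp_genotypic\tp_bonferroni\n"
        + "\n".join(body)
        + "\n"
    )
    summary["association_min_p"] = min(pvals)
    summary["association_any_significant_bonferroni"] = any(corr.reject)


@_stage("ld")
def _run_ld(table: GenotypeTable, config: RunConfig, out: Path, summary: dict):
    mat = ld_matrix(table, seed=config.seed)
    mat.to_tsv(out / "ld_matrix.tsv")
    (out / "ld_triangle.txt").write_text(
        mat.render_triangle("r2") + "\n\n" + mat.render_triangle("dprime") + "\n"
    )
    if len(table.snp_ids) <= 8:
        dist = em_haplotype_freqs(table, table.snp_ids, seed=config.seed)
        with open(out / "haplotypes.tsv", "w") as fh:
            fh.write("haplotype\tfrequency\n")
            for hap, f in dist.freqs.items():
                fh.write(f"{hap}\t{f:.3f}\n")
        summary["haplotypes"] = {h: round(f, 3) for h, f in dist.freqs.items()}
    return mat


@_stage("blocks")
def _run_blocks(table: GenotypeTable, config: RunConfig, out: Path, summary: dict) -> None:
    results = {
        "confidence_interval": blocks_confidence_interval(table, seed=config.seed),
        "four_gamete": blocks_four_gamete(table, seed=config.seed),
        "solid_spine": blocks_solid_spine(table, seed=config.seed),
    }
    lines = ["method\tblock_index\tfirst_snp\tlast_snp\tn_snps\tdiagnostics"]
    for method, bs in results.items():
        diag = "; ".join(bs.diagnostics) or "."
        for b, (first, last) in enumerate(bs.blocks):
            lines.append(
                f"{method}\t{b}\t{bs.snp_ids[first]}\t{bs.snp_ids[last]}\t"
                f"{last - first + 1}\t{diag}"
            )
        if not bs.blocks:
            lines.append(f"{method}\t.\t.\t.\t0\t.")
    (out / "blocks.tsv").write_text("\n".join(lines) + "\n")
    summary["blocks"] = {m: bs.block_members() for m, bs in results.items()}


@_stage("compound")
def _run_compound(
    table: GenotypeTable,
    labels: CohortLabels | None,
    config: RunConfig,
    out: Path,
    summary: dict,
) -> None:
    snp_a, snp_b = config.snp_pair
    tables = compound_table(
        table, snp_a, snp_b, labels,
        index_allele_a=config.index_allele_a,
        index_allele_b=config.index_allele_b,
    )
    obs = tables["all"]
    freq_a = obs.index_allele_frequency("a")
    freq_b = obs.index_allele_frequency("b")
    if config.fidelity_round:
        freq_a, freq_b = round(freq_a, 2), round(freq_b, 2)
    lines = [
        "genotype_a\tgenotype_b\tobserved\texpected_naive\tp_naive\t"
        "expected_hwe\tp_hwe"
    ]
    n = obs.n
    exp_naive = expected_counts(freq_a, freq_b, n, "naive_product")
    exp_hwe = expected_counts(freq_a, freq_b, n, "hwe_multinomial")
    tests_naive = observed_vs_expected_test(obs.counts, exp_naive)
    tests_hwe = observed_vs_expected_test(obs.counts, exp_hwe)
    for i, ca in enumerate(GENO_LABELS):
        for j, cb in enumerate(GENO_LABELS):
            lines.append(
                f"{ca}x{obs.index_allele_a}\t{cb}x{obs.index_allele_b}\t"
                f"{obs.counts[i, j]}\t{exp_naive.expected[i, j]:.1f}\t"
                f"{tests_naive[(i, j)].p_value:.3e}\t"
                f"{exp_hwe.expected[i, j]:.1f}\t{tests_hwe[(i, j)].p_value:.3e}"
            )
    (out / "compound.tsv").write_text("\n".join(lines) + "\n")
    summary["compound"] = {
        "freq_a": freq_a,
        "freq_b": freq_b,
        "n": n,
        "observed_top_left": int(obs.counts[0, 0]),
        "expected_naive_top_left": round(float(exp_naive.expected[0, 0]), 1),
        "p_top_left": tests_naive[(0, 0)].p_value,
    }
    # per-sample expression annotation for the canonical ERAP2 pair
    if {snp_a, snp_b} == {"rs2248374", "rs2549782"}:
        a374 = snp_a if snp_a == "rs2248374" else snp_b
        a782 = snp_b if a374 == snp_a else snp_a
        with open(out / "expression.csv", "w") as fh:
            fh.write("sample,erap2_dosage,n392_dosage\n")
            for i, sample in enumerate(table.samples):
                ga = table.calls[i, table.snp_index(a374)]
                gb = table.calls[i, table.snp_index(a782)]
                if ga < 0 or gb < 0:
                    fh.write(f"{sample},NA,NA\n")
                    continue
                pred = predict_expression(int(ga), int(gb))
                fh.write(f"{sample},{pred.erap2_dosage},{pred.n392_dosage}\n")


@_stage("epistasis")
def _run_epistasis(
    table: GenotypeTable,
    labels: CohortLabels,
    config: RunConfig,
    out: Path,
    summary: dict,
) -> None:
    snp_a, snp_b = config.snp_pair
    res = interaction_test(table, snp_a, snp_b, labels)
    (out / "epistasis.tsv").write_text(
        "snp_a\tsnp_b\tcoding\tlrt_stat\tp\n"
        f"{snp_a}\t{snp_b}\tadditive\t{res.statistic:.4f}\t{res.p_value:.3e}\n"
    )
    summary["epistasis_p"] = res.p_value
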