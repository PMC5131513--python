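"""Pipeline orchestration: the fixture reproduction suite and the
end-to-end multi-stage analysis over files.

``run_fixture_suite`` recomputes every statistic that can be derived from
the packaged published tables — assignment concordance, marker-set
congruence (R^2), Wilcoxon signed-rank comparisons, Mantel correlations of
niche overlap with genetic distance, allele-count summaries, and the
(delta mu)^2 divergence dating of the deepest split — and compares each to
its published value.

``run_full_pipeline`` runs the stages genotypes -> concordance -> stats ->
tree -> haploweb -> niche -> Mantel over user-supplied files, writing every
output with a provenance header (inputs, parameters, seed, version).
"""

from __future__ import annotations

import datetime
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import __version__
from . import cluster_concord, fixtures, niche_overlap, phylo_time, popstats
from . import haploweb as hw
from .geno_io import (
    SNP,
    SSR,
    read_genotype_table,
    read_membership_matrix,
    read_phased_fasta,
    write_distance_csv,
)

__all__ = ["run_fixture_suite", "run_full_pipeline"]


def _check(name: str, value, expected, passed: bool) -> dict:
    return {"name": name, "value": value, "expected": expected, "pass": bool(passed)}


def run_fixture_suite(seed: int = 0, n_perm: int = 10000) -> dict:
    """Recompute all statistics derivable from the packaged published tables.

    Returns a report with one entry per check; ``seed`` and ``n_perm``
    control the Mantel permutation tests (whose p-values are reported but
    not themselves checked — only r and the regression slope are).
    """
    table1 = fixtures.load_crosstab_fixture()
    t3 = fixtures.load_distance_fixtures()
    checks: list[dict] = []

    conc = cluster_concord.concordance(table1)
    checks.append(
        _check("concordant_individuals", conc["n_concordant"], 380,
               conc["n_concordant"] == 380)
    )
    pct = 100.0 * conc["fraction"]
    checks.append(_check("concordance_percent", round(pct, 1), 87, round(pct) == 87))

    r2_ds = popstats.pearson_ols(t3["ds_ssr"].condensed(), t3["ds_snp"].condensed())["r2"]
    checks.append(_check("r2_ds_markers", round(r2_ds, 4), 0.13, abs(r2_ds - 0.13) <= 0.005))
    r2_fst = popstats.pearson_ols(t3["fst_ssr"].condensed(), t3["fst_snp"].condensed())["r2"]
    checks.append(_check("r2_fst_markers", round(r2_fst, 4), 0.41, abs(r2_fst - 0.41) <= 0.005))

    z_fst = popstats.wilcoxon_signed_rank_z(
        t3["fst_ssr"].condensed(), t3["fst_snp"].condensed()
    )["abs_z"]
    z_ds = popstats.wilcoxon_signed_rank_z(
        t3["ds_ssr"].condensed(), t3["ds_snp"].condensed()
    )["abs_z"]
    z_small, z_large = sorted((z_fst, z_ds))
    checks.append(
        _check("wilcoxon_abs_z_smaller", round(z_small, 4), 2.38, abs(z_small - 2.38) <= 0.01)
    )
    checks.append(
        _check("wilcoxon_abs_z_larger", round(z_large, 4), 3.24, abs(z_large - 3.24) <= 0.01)
    )

    m_ds = niche_overlap.mantel_test(t3["ds_ssr"], t3["niche_d"], n_perm, seed)
    checks.append(
        _check(
            "mantel_ds_niche",
            {"r": round(m_ds.r, 4), "slope": round(m_ds.slope, 4), "p": round(m_ds.p, 4)},
            {"r": -0.39, "slope": -0.131},
            abs(m_ds.r - (-0.39)) <= 0.005 and abs(m_ds.slope - (-0.131)) <= 0.0005,
        )
    )
    m_dmu = niche_overlap.mantel_test(t3["dmu2_ssr"], t3["niche_d"], n_perm, seed)
    checks.append(
        _check(
            "mantel_dmu2_niche",
            {"r": round(m_dmu.r, 4), "slope": round(m_dmu.slope, 4), "p": round(m_dmu.p, 4)},
            {"r": -0.581, "slope": -0.022},
            abs(m_dmu.r - (-0.581)) <= 0.0005 and abs(m_dmu.slope - (-0.022)) <= 0.0005,
        )
    )

    (n_ssr, a_ssr) = fixtures.PUBLISHED_ALLELE_TOTALS["SSR"]
    (n_snp, a_snp) = fixtures.PUBLISHED_ALLELE_TOTALS["SNP"]
    ratio = round(a_snp / a_ssr, 2)
    checks.append(_check("allele_ratio_snp_ssr", ratio, 2.06, ratio == 2.06))
    checks.append(
        _check("ssr_alleles_minus_loci", a_ssr - n_ssr, 58, a_ssr - n_ssr == 58)
    )

    deepest = max(t3["dmu2_ssr"].pair_labels(), key=lambda p: t3["dmu2_ssr"].value(*p))
    est = phylo_time.divergence_time(t3["dmu2_ssr"].value(*deepest), pair=deepest)
    checks.append(
        _check(
            "divergence_k2k6_generations",
            {"pair": list(deepest), "low": est.generations[0], "high": est.generations[1]},
            {"low": 7050.0, "high": 1.41e6},
            deepest == ("K2", "K6")
            and abs(est.generations[0] - 7050.0) <= 1.0
            and abs(est.generations[1] - 1.41e6) <= 1e3,
        )
    )

    return {
        "n_checks": len(checks),
        "n_passed": sum(c["pass"] for c in checks),
        "seed": seed,
        "n_permutations": n_perm,
        "checks": checks,
    }


# ---------------------------------------------------------------------------
# full pipeline over files
# ---------------------------------------------------------------------------


def _provenance(cfg: Mapping, stage: str) -> str:
    stamp = datetime.datetime.now().isoformat(timespec="seconds")
    lines = [f"# cryptodelim v{__version__} stage={stage} time={stamp}"]
    for key in sorted(cfg):
        lines.append(f"# param {key} = {cfg[key]}")
    return "\n".join(lines) + "\n"


def _write_with_header(path: Path, header: str, body: str) -> None:
    path.write_text(header + body, encoding="utf-8")


def run_full_pipeline(cfg: Mapping) -> Path:
    """Run all stages over the files named in ``cfg``; returns the output dir.

    Recognised keys: ``genotypes, q_snp, q_ssr, haplotypes, occurrences,
    background, out_dir, threshold, bootstrap, seed, grid, permutations``
    and ``skip_niche``.  Stage failures raise with a stage-tagged message.
    """
    cfg = dict(cfg)
    out = Path(cfg.get("out_dir", "cryptodelim_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg.get("seed")
    if seed is None:
        raise ValueError("config: a seed is required (bootstrap and Mantel stages)")
    threshold = float(cfg.get("threshold", 0.5))

    def stage(name: str):
        def wrap(exc: Exception):
            return RuntimeError(f"stage {name!r} failed: {exc}")
        return wrap

    # --- genotypes ------------------------------------------------------
    try:
        geno = read_genotype_table(cfg["genotypes"])
    except Exception as exc:  # noqa: BLE001
        raise stage("genotypes")(exc) from exc

    # --- concordance ----------------------------------------------------
    try:
        q_a = read_membership_matrix(cfg["q_snp"])
        q_b = read_membership_matrix(cfg["q_ssr"])
        assign_a = cluster_concord.assign_clusters(q_a, threshold)
        assign_b = cluster_concord.assign_clusters(q_b, threshold)
        table = cluster_concord.cross_tabulate(assign_a, assign_b)
        conc = cluster_concord.concordance(table)
        header = _provenance(cfg, "concord")
        _write_with_header(
            out / "concordance.csv",
            header
            + f"# n_concordant = {conc['n_concordant']}\n"
            + f"# fraction = {conc['fraction']:.4f}\n",
            table.to_dataframe().to_csv(),
        )
    except Exception as exc:  # noqa: BLE001
        raise stage("concord")(exc) from exc

    # --- stats ----------------------------------------------------------
    try:
        groups = {i: c for i, c in assign_a.defined().items()}
        div_rows = []
        for mtype in (SSR, SNP):
            if not geno.locus_indices(mtype):
                continue
            for d in popstats.diversity_stats(geno, groups, mtype):
                div_rows.append(
                    {"group": d.group, "marker": mtype, "NAe": d.NAe, "AR": d.AR,
                     "He": d.He, "Npl": d.Npl, "k_used": d.k_used}
                )
        pd.DataFrame(div_rows).to_csv(out / "diversity.csv", index=False)
        for metric, mtype, tag in (
            ("FST", SSR, "fst_ssr"), ("DS", SSR, "ds_ssr"),
            ("FST", SNP, "fst_snp"), ("DS", SNP, "ds_snp"),
            ("DELTA_MU_SQ", SSR, "dmu2_ssr"),
        ):
            if not geno.locus_indices(mtype):
                continue
            mat = popstats.pairwise_matrix(geno, groups, metric, mtype)
            write_distance_csv(mat, out / f"dist_{tag}.csv")
    except Exception as exc:  # noqa: BLE001
        raise stage("stats")(exc) from exc

    # --- tree -----------------------------------------------------------
    try:
        tree = phylo_time.bootstrap_supports(
            geno, groups, metric="DS", B=int(cfg.get("bootstrap", 1000)),
            seed=int(seed), marker_type=SSR,
        )
        _write_with_header(out / "tree_ds_ssr.nwk", _provenance(cfg, "tree"),
                           tree.newick() + "\n")
    except Exception as exc:  # noqa: BLE001
        raise stage("tree")(exc) from exc

    # --- haploweb -------------------------------------------------------
    try:
        if "haplotypes" in cfg:
            phs = read_phased_fasta(cfg["haplotypes"])
            web = hw.build_haploweb(phs)
            part = hw.find_ffrs(web)
            rows = [
                {"individual": ind, "ffr": ffr}
                for ind, ffr in sorted(part.ffr_of_individual().items())
            ]
            pd.DataFrame(rows).to_csv(out / "ffr_membership.csv", index=False)
            edge_rows = [
                {"hap_a": a, "hap_b": b, "n_heterozygotes": data["weight"]}
                for a, b, data in web.graph.edges(data=True)
            ]
            pd.DataFrame(edge_rows, columns=["hap_a", "hap_b", "n_heterozygotes"]).to_csv(
                out / "haploweb_edges.csv", index=False
            )
            import networkx as nx

            nx.write_graphml(web.graph, out / "haploweb.graphml")
    except Exception as exc:  # noqa: BLE001
        raise stage("haploweb")(exc) from exc

    # --- niche + mantel -------------------------------------------------
    if not cfg.get("skip_niche") and "occurrences" in cfg:
        try:
            occ_df = pd.read_csv(cfg["occurrences"])
            background = pd.read_csv(cfg["background"]).to_numpy(dtype=float)
            occ = niche_overlap.EnvOccurrenceSet(occ_df, background)
            d_mat = niche_overlap.niche_overlap_matrix(occ, R=int(cfg.get("grid", 100)))
            write_distance_csv(d_mat, out / "niche_d.csv")
            n_perm = int(cfg.get("permutations", 10000))
            results = []
            for tag in ("ds_ssr", "dmu2_ssr"):
                gen_path = out / f"dist_{tag}.csv"
                if not gen_path.exists():
                    continue
                from .geno_io import read_distance_csv

                gen = read_distance_csv(gen_path)
                common = [l for l in gen.labels if l in d_mat.labels]
                if len(common) < 4:
                    continue
                res = niche_overlap.mantel_test(
                    gen.reordered(common), d_mat.reordered(common), n_perm, int(seed)
                )
                results.append(
                    {"genetic": tag, "r": res.r, "slope": res.slope, "p": res.p,
                     "n_permutations": res.n_permutations}
                )
            pd.DataFrame(results).to_csv(out / "mantel.csv", index=False)
        except Exception as exc:  # noqa: BLE001
            raise stage("niche")(exc) from exc
    return out
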