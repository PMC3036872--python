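"""End-to-end analysis pipeline over one alignment + population map.

Stages (each skippable): haplotype summary and site classification;
per-population and pooled diversity and neutrality tests; pooled mismatch
distribution with sudden-expansion fit and expansion-time conversion;
AMOVA and pairwise Phi_ST on squared model distances; the haplotype minimum
spanning network; and optionally the IM sampler on a two-group pooling.
All outputs are CSV/JSON files in the configured output directory plus a
machine-readable ``report.json``.  A single master seed deterministically
derives one seed per stage, so stages can be toggled without changing the
randomness of the others.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import alignio, diversity, mismatch, neutrality
from .amova import amova, pairwise_phist
from .im import DemographicScaling, IMPriors, im_mcmc, scale_to_demographic_units
from .network import minimum_spanning_network, network_to_dataframe

log = logging.getLogger("mtpopgen")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    fasta: str
    popmap: str
    outdir: str = "mtpopgen_out"
    mask_ranges: list[tuple[int, int]] = field(default_factory=list)
    distance_model: str = "TN93+G"
    gamma_alpha: float = 0.61
    invariant_fraction: float = 0.0
    mu_site_per_year: float = 1.9e-7
    generation_years: float = 1.0
    neutrality_reps: int = 1000
    amova_perms: int = 5000
    pairwise_perms: int = 1000
    mismatch_boot: int = 200
    groups: dict[str, str] | None = None
    run_im: bool = False
    im_priors: dict[str, float] = field(default_factory=dict)
    im_burn: int = 50_000
    im_steps: int = 500_000
    im_thin: int = 100
    seed: int = 1

    def stage_seed(self, stage: str) -> int:
        ss = np.random.SeedSequence([self.seed, abs(hash(stage)) % 2**31])
        return int(ss.generate_state(1)[0] % 2**31)


def _div_neutrality_row(aln, label, cfg):
    diffs, comp = diversity.pairwise_differences(aln)
    iu = np.triu_indices(aln.n, k=1)
    k_mean = float(diffs[iu].mean())
    sites = alignio.classify_sites(aln)
    S = sites.S - sites.n_indels  # substitution polymorphism only
    tbl = alignio.collapse_haplotypes(
        aln, alignio.PopulationMap({s: label for s in aln.ids})
    )
    h, sd_h = diversity.haplotype_diversity(tbl.total_counts())
    pi, sd_pi = diversity.nucleotide_diversity(aln)
    row = {
        "population": label, "n": aln.n, "K": tbl.k, "S": S,
        "h": h, "sd_h": sd_h, "pi_pct": 100 * pi, "sd_pi_pct": 100 * sd_pi,
        "k_mean": k_mean,
    }
    if aln.n >= 4 and S >= 1:
        res = neutrality.neutrality_pvalues(
            aln.n, S, k_mean, tbl.k, cfg.neutrality_reps, cfg.stage_seed(f"neut-{label}")
        )
        row.update({"D": res.D, "p_D": res.p_D, "Fs": res.Fs, "p_Fs": res.p_Fs})
    return row, diffs


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage; returns the report dict (also written)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(config)}

    aln, popmap = alignio.read_alignment(config.fasta, config.popmap)
    aln = alignio.mask_sites(aln, config.mask_ranges)
    log.info("alignment: %d sequences x %d sites", aln.n, aln.length)

    # --- haplotypes and sites
    tbl = alignio.collapse_haplotypes(aln, popmap)
    tbl.write_csv(out / "haplotype_table.csv")
    n_shared, n_private, pct = alignio.shared_private_summary(tbl)
    sites = alignio.classify_sites(aln)
    report["haplotypes"] = {
        "K": tbl.k, "n": tbl.n, "shared": n_shared, "private": n_private,
        "pct_private": pct,
    }
    report["sites"] = {
        "S": sites.S, "transitions": sites.n_transitions,
        "transversions": sites.n_transversions, "indels": sites.n_indels,
        "base_composition": sites.base_composition,
    }

    # --- diversity + neutrality per population and pooled
    rows = []
    pooled_row, pooled_diffs = _div_neutrality_row(aln, "Total", config)
    for pop in popmap.populations:
        ids = [s for s in aln.ids if popmap.of(s) == pop]
        sub = aln.subset(ids)
        if sub.n < 2:
            log.warning("population %s has <2 samples; skipped", pop)
            continue
        row, _ = _div_neutrality_row(sub, pop, config)
        rows.append(row)
    rows.append(pooled_row)
    div_df = pd.DataFrame(rows)
    div_df.to_csv(out / "diversity_neutrality.csv", index=False)
    report["diversity"] = div_df.to_dict(orient="records")

    # --- mismatch (pooled)
    obs = mismatch.observed_mismatch(pooled_diffs)
    fit = mismatch.fit_sudden_expansion(
        obs, aln.n, seed=config.stage_seed("mismatch"), n_boot=config.mismatch_boot
    )
    scaling = mismatch.TimeScaling(
        config.mu_site_per_year, aln.length, config.generation_years
    )
    years = mismatch.tau_to_years(fit.tau, scaling)
    exp_v = mismatch.expected_mismatch(fit.tau, fit.theta0, fit.theta1, len(obs) - 1)
    pd.DataFrame({"differences": np.arange(len(obs)), "observed": obs, "expected": exp_v}).to_csv(
        out / "mismatch_curve.csv", index=False
    )
    report["mismatch"] = {
        "tau": fit.tau, "theta0": fit.theta0, "theta1": fit.theta1,
        "SSD": fit.SSD, "p_SSD": fit.p_SSD, "raggedness": fit.raggedness,
        "p_raggedness": fit.p_raggedness, "ci95_tau": list(fit.ci95_tau),
        "expansion_years": years,
        "expansion_years_rounded": round(years / 100.0) * 100.0,
    }

    # --- structure: AMOVA + pairwise Phi_ST on squared model distances
    params = diversity.DistanceModelParams(config.distance_model, config.gamma_alpha,
                                           config.invariant_fraction)
    d = diversity.distance_matrix(aln, params)
    labels = popmap.labels_for(aln.ids)
    res = amova(d**2, labels, groups=config.groups, n_perms=config.amova_perms,
                seed=config.stage_seed("amova"))
    res.table().to_csv(out / "amova.csv", index=False)
    report["amova"] = {
        "phi_st": res.phi_st, "p": res.p_value, "phi_ct": res.phi_ct,
        "p_ct": res.p_ct, "phi_sc": res.phi_sc,
        "percent": res.percent, "n_perms": res.n_perms,
    }
    pw = pairwise_phist(d**2, labels, n_perms=config.pairwise_perms,
                        seed=config.stage_seed("pairwise"))
    pw.phi_st.to_csv(out / "pairwise_phist.csv")
    pw.p_values.to_csv(out / "pairwise_phist_pvalues.csv")
    report["pairwise_phist"] = {
        "phi_st": pw.phi_st.where(pd.notna(pw.phi_st), None).to_dict(),
        "p_values": pw.p_values.where(pd.notna(pw.p_values), None).to_dict(),
    }

    # --- haplotype network on haplotype-level difference counts
    hap_aln = alignio.Alignment(
        tuple(f"h{i}" for i in tbl.counts.index), tbl.sequences
    )
    hap_diffs, _ = diversity.pairwise_differences(hap_aln)
    edges = minimum_spanning_network(tbl, hap_diffs)
    network_to_dataframe(edges).to_csv(out / "network_edges.csv", index=False)
    report["network"] = {"n_edges": len(edges),
                         "n_mst_edges": sum(e.in_mst for e in edges)}

    # --- IM (optional, two groups required)
    if config.run_im:
        if not config.groups:
            raise ValueError("IM stage needs a two-group pooling in config.groups")
        group_names = list(dict.fromkeys(config.groups.values()))
        if len(group_names) != 2:
            raise ValueError("IM stage needs exactly two groups")
        merged = alignio.PopulationMap(
            {s: config.groups[popmap.of(s)] for s in aln.ids}, tuple(group_names)
        )
        priors = IMPriors(**config.im_priors) if config.im_priors else IMPriors()
        post = im_mcmc(
            aln, merged, priors, n_burn=config.im_burn, n_steps=config.im_steps,
            thin=config.im_thin, seed=config.stage_seed("im"),
        )
        post.samples.to_csv(out / "im_trace.tsv", sep="\t", index=False)
        for name, (edges_, mass) in post.histograms.items():
            pd.DataFrame({"bin_lo": edges_[:-1], "bin_hi": edges_[1:], "mass": mass}).to_csv(
                out / f"im_hist_{name}.csv", index=False
            )
        scaling_im = DemographicScaling(
            u=config.mu_site_per_year * aln.length * config.generation_years,
            generation_years=config.generation_years,
        )
        report["im"] = {
            "modes": post.modes, "hpd95": {k: list(v) for k, v in post.hpd95.items()},
            "ess": post.ess, "n_recorded": post.n_recorded,
            "converged": post.converged,
            "demographic": scale_to_demographic_units(post, scaling_im),
        }

    (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
    return report
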