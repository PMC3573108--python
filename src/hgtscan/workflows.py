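"""End-to-end study reproductions on synthetic data.

Each function runs one complete evidence stream of the pipeline on a
generated dataset with known truth and reports recovery statistics:
the published-table summary counts, transfer-call recovery and false
positives, AU-test calibration and power, the organellar/nuclear
copy-number contrast, recombination-breakpoint localisation, and
transfer-timing concordance.  The acceptance script and the heavier
tests are thin callers of these functions.
"""

from __future__ import annotations

import numpy as np

from .autest import au_test
from .classify import analyze_gene, summarize_calls
from .evidence import compare_compartments, estimate_copy_number
from .io import load_reference_calls
from .phylo import constrained_ml, gtr_gamma_loglik, optimize_tree
from .simulate import (Scenario, TransferEvent, generate_dataset,
                       simulate_alignment, simulate_chimeric_alignment,
                       simulate_gene_tree, simulate_reads, panel_15,
                       species_tree_15)
from .timing import classify_timing, localize_breakpoint_from_alignment

#: reduced sub-panels used where a single parasite (or one per genus)
#: suffices; smaller trees keep per-gene inference cheap
SUBPANEL_9 = ["Cycas", "Spirodela", "Oryza", "Arabidopsis", "Ricinus", "Leea",
              "Vitis", "Tetrastigma_A", "Sapria"]
SUBPANEL_10 = ["Cycas", "Oryza", "Ricinus", "Leea", "Vitis", "Tetrastigma_A",
               "Tetrastigma_B", "Rafflesia_A", "Rafflesia_B", "Sapria"]


def reference_table_counts() -> dict:
    """Summary counts of the packaged published call table."""
    calls = load_reference_calls()
    out = {}
    species = {"rafflesia_cantleyi": "R. cantleyi",
               "rafflesia_tuanmudae": "R. tuan-mudae",
               "sapria_himalayana": "S. himalayana"}
    for key, name in species.items():
        for thr in (70, 50):
            s = summarize_calls(calls, thr, species=name,
                                compartment="mitochondrial")
            out[f"hgt_sequences_{key}_bp{thr}"] = s.n_hgt_sequences
    for thr in (70, 50):
        s = summarize_calls(calls, thr, compartment="mitochondrial")
        out[f"hgt_mito_genes_bp{thr}"] = s.n_hgt_genes
        out[f"dual_homolog_genes_bp{thr}"] = s.n_dual_homolog_genes
    s70 = summarize_calls(calls, 70, compartment="mitochondrial")
    out["au_rejections_bp70"] = s70.n_au_rejections
    out["plastid_origin_genes_bp70"] = summarize_calls(
        calls, 70, compartment="plastid_origin").n_hgt_genes
    out["transgene_rows_total"] = sum(1 for c in calls if c.identity == "HGT")
    out["transgene_rows_rafflesia"] = sum(
        1 for c in calls if c.identity == "HGT" and c.species.startswith("R."))
    out["transgene_rows_sapria"] = sum(
        1 for c in calls if c.identity == "HGT" and c.species.startswith("S."))
    for sp_key, name in species.items():
        s50 = summarize_calls(calls, 50, species=name, compartment="mitochondrial")
        out[f"intact_transgenes_{sp_key}"] = s50.n_intact_transgenes
    return out


def classification_recovery(seed: int = 0, scenario: Scenario | None = None,
                            reps: int = 100, threshold: int = 70) -> dict:
    """Run the full detection pipeline on a generated study and compare
    calls with the simulation truth.

    A transferred gene counts as recovered when every recipient's
    sequence is called HGT; a vertical gene when every parasite
    sequence is called VGT.  A vertical gene with any HGT call is a
    false positive (the autotroph-control analogue)."""
    scenario = scenario or Scenario()
    sim = generate_dataset(scenario, seed=seed)
    recovered = n_vertical = false_pos = 0
    calls_by_gene = {}
    for aln in sim.alignments:
        truth = sim.truth.genes[aln.gene_id]
        _, calls = analyze_gene(aln, sim.panel, reps=reps, seed=seed + 1,
                                threshold=threshold)
        calls_by_gene[aln.gene_id] = calls
        if truth.history == "transferred":
            recipients = set().union(*(set(e.recipient_clade)
                                       for e in truth.events))
            ok = all(c.identity == "HGT" for c in calls
                     if c.species in recipients)
        else:
            n_vertical += 1
            ok = all(c.identity == "VGT" for c in calls)
            if any(c.identity == "HGT" for c in calls):
                false_pos += 1
        recovered += ok
    n = len(sim.alignments)
    return {
        "n_genes": n,
        "recovery_rate": recovered / n,
        "false_positive_rate": false_pos / n_vertical if n_vertical else 0.0,
        "n_vertical": n_vertical,
        "calls_by_gene": calls_by_gene,
    }


def _au_one_gene(seed: int, transfer: bool, n_sites: int,
                 rell_reps: int) -> bool:
    """Simulate one gene on the 8-taxon sub-panel and AU-test the
    vertical hypothesis; returns whether it was rejected at 0.05."""
    tree = species_tree_15().prune_to(SUBPANEL_9)
    params = Scenario().params
    if transfer:
        event = TransferEvent("g", frozenset({"Sapria"}),
                              frozenset({"Tetrastigma_A"}), 30.0 / 300.0)
        gtree = simulate_gene_tree(tree, event)
    else:
        gtree = tree
    aln = simulate_alignment(gtree.scale_to_substitutions(1e-3), params,
                             n_sites, seed=seed)
    best = optimize_tree(aln)
    cons = constrained_ml(aln, best.params, {"Ricinus", "Sapria"},
                          estimate_model=False)
    sll_c = gtr_gamma_loglik(aln, cons, best.params)
    sll_u = gtr_gamma_loglik(aln, best, best.params)
    return au_test(sll_c.site_loglik, sll_u.site_loglik,
                   reps=rell_reps, seed=seed).rejects


def au_calibration(seed: int = 0, n_genes: int = 100, transfer: bool = False,
                   n_sites: int = 1000, rell_reps: int = 1000) -> dict:
    """AU rejection rate over simulated genes: with the vertical
    constraint true it should stay near (below) the nominal level; for
    a strongly supported host-nested transfer it should approach 1."""
    rejections = sum(_au_one_gene(seed * 1000 + i, transfer, n_sites, rell_reps)
                     for i in range(n_genes))
    return {"n_genes": n_genes, "rejection_rate": rejections / n_genes}


def copy_number_recovery(seed: int = 0, n_genes_per_group: int = 20,
                         gene_length: int = 2000,
                         scenario: Scenario | None = None) -> dict:
    """Simulate reads at the organellar/nuclear depth contrast and
    recover the ratio by unique k-mer mapping plus Welch's t."""
    scenario = scenario or Scenario()
    rng = np.random.default_rng(seed)
    genes, depths, compartment = {}, {}, {}
    for i in range(n_genes_per_group):
        for prefix, depth in (("mt", scenario.organellar_depth),
                              ("nuc", scenario.nuclear_depth)):
            gid = f"{prefix}{i:02d}"
            genes[gid] = "".join(rng.choice(list("ACGT"), gene_length))
            depths[gid] = depth
            compartment[gid] = "mitochondrial" if prefix == "mt" else "nuclear"
    reads = simulate_reads(genes, depths, scenario.read_len,
                           scenario.error_rate, seed=rng)
    records = estimate_copy_number(reads, genes, k=25,
                                   compartment_of=compartment)
    mito = [r for r in records if r.compartment == "mitochondrial"]
    nuc = [r for r in records if r.compartment == "nuclear"]
    welch = compare_compartments(mito, nuc)
    return {
        "true_ratio": scenario.organellar_depth / scenario.nuclear_depth,
        "estimated_fold": welch.fold,
        "p_value": welch.p_value,
        "n_genes": 2 * n_genes_per_group,
    }


def breakpoint_recovery(seed: int = 0, n_chimeras: int = 20,
                        region_len: int = 600, reps: int = 100,
                        threshold: int = 70) -> dict:
    """Chimeric genes spliced at a known column: how often is the
    breakpoint localised to an interval containing the true junction?"""
    tree = species_tree_15().prune_to(SUBPANEL_9)
    panel = panel_15()
    params = Scenario().params
    regions = [("exonA", 0, region_len),
               ("intronAB", region_len, 2 * region_len),
               ("exonB", 2 * region_len, 3 * region_len)]
    event = TransferEvent("chimera", frozenset({"Sapria"}),
                          frozenset({"Tetrastigma_A"}), 30.0 / 300.0)
    hits = exact = 0
    for i in range(n_chimeras):
        aln = simulate_chimeric_alignment(tree, event, params, 1e-3, regions,
                                          {"exonA"}, seed=seed * 977 + i)
        report = localize_breakpoint_from_alignment(
            aln, panel, "Sapria", threshold=threshold, reps=reps,
            seed=seed * 977 + i)
        contains = any(lo <= region_len <= hi for lo, hi in report.breakpoints)
        hits += contains
        exact += (region_len, region_len) in report.breakpoints
    return {"n_chimeras": n_chimeras, "recovered": hits, "exact": exact,
            "recovery_rate": hits / n_chimeras}


def timing_concordance(seed: int = 0, n_histories: int = 30,
                       n_sites: int = 1000, reps: int = 100) -> dict:
    """Ancient / recent / repeated verdicts against simulation truth."""
    tree = species_tree_15().prune_to(SUBPANEL_10)
    panel = panel_15()
    params = Scenario().params
    hosts = frozenset({"Leea", "Vitis", "Tetrastigma_A", "Tetrastigma_B"})
    tets = frozenset({"Tetrastigma_A", "Tetrastigma_B"})
    vitis = frozenset({"Vitis"})
    rafflesia = frozenset({"Rafflesia_A", "Rafflesia_B"})
    all_parasites = frozenset({"Rafflesia_A", "Rafflesia_B", "Sapria"})
    cases = [
        ([TransferEvent("g", all_parasites, hosts, 110 / 300)], "ancient"),
        ([TransferEvent("g", frozenset({"Sapria"}), tets, 30 / 300)], "recent"),
        ([TransferEvent("g", rafflesia, tets, 40 / 300),
          TransferEvent("g", frozenset({"Sapria"}), vitis, 30 / 300)],
         "repeated_independent"),
    ]
    correct = scored = 0
    for i in range(n_histories):
        events, expected = cases[i % len(cases)]
        gtree = simulate_gene_tree(tree, events)
        aln = simulate_alignment(gtree.scale_to_substitutions(1e-3), params,
                                 n_sites, seed=seed * 7919 + i)
        stree, calls = analyze_gene(aln, panel, reps=reps, seed=seed * 7919 + i)
        hgt_calls = [c for c in calls if c.identity == "HGT"]
        if not hgt_calls:
            scored += 1       # a missed transfer counts as a miss
            continue
        verdict = classify_timing(stree, hgt_calls, panel)
        scored += 1
        correct += verdict.verdict == expected
    return {"n_histories": scored, "correct": correct,
            "concordance": correct / scored}
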