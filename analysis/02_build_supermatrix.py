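"""Merge samples into species, filter genes, concatenate, bin by rate.

Reads the per-gene alignments written by 01_simulate_inputs.py, applies
the individual-level filters (< 0.1% ambiguous, < 60% missing, >= 95%
of samples), then merges conspecific samples and applies the stricter
species-level filters (< 40% missing, 100% of species).  Survivors are
concatenated into partitioned supermatrices and the species-level genes
are binned by a mean pairwise p-distance rate proxy.
"""

from __future__ import annotations

import argparse
from pathlib import Path

from orodiversify.dataset_builder import (
    FilterThresholds,
    OrthogroupSet,
    bin_by_rate,
    concatenate,
    filter_orthogroups,
    gene_rates,
    merge_to_species,
)
from orodiversify.io_model import read_fasta, read_sample_map, write_fasta


def _write_supermatrix(sm, stem: Path):
    write_fasta(sm.alignment, stem.with_suffix(".fasta"))
    with open(stem.with_suffix(".partitions.tsv"), "w") as fh:
        fh.write("gene\tstart\tend\n")
        for gid, (lo, hi) in sorted(sm.partitions.items()):
            fh.write(f"{gid}\t{lo}\t{hi}\n")


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--indir", type=Path, default=Path("results/inputs"))
    ap.add_argument("--outdir", type=Path, default=Path("results/dataset"))
    ap.add_argument("--n-bins", type=int, default=10,
                    help="rate bins (near-equal sizes)")
    args = ap.parse_args(argv)
    args.outdir.mkdir(parents=True, exist_ok=True)

    genes = {
        p.stem: read_fasta(p)
        for p in sorted((args.indir / "orthogroups").glob("*.fasta"))
    }
    smap = read_sample_map(args.indir / "samples.tsv")
    ogs = OrthogroupSet(genes, sample_map=smap, level="individual")

    kept_ind, report_ind = filter_orthogroups(
        ogs, FilterThresholds.individual_level(), full_taxa=list(smap)
    )
    report_ind.to_csv(args.outdir / "filter_report_individual.tsv", sep="\t")
    sm_ind = concatenate(kept_ind)
    _write_supermatrix(sm_ind, args.outdir / "supermatrix_individual")
    print(f"individual level: {len(kept_ind.genes)}/{len(genes)} genes pass; "
          f"supermatrix {sm_ind.alignment.length} nt, "
          f"{100 * sm_ind.completeness:.1f}% complete")

    species_ogs = merge_to_species(ogs)
    kept_sp, report_sp = filter_orthogroups(
        species_ogs, FilterThresholds.species_level(),
        full_taxa=sorted(set(smap.values())),
    )
    report_sp.to_csv(args.outdir / "filter_report_species.tsv", sep="\t")
    if not kept_sp.genes:
        print("species level: no genes pass the strict filters at this scale")
        return
    sm_sp = concatenate(kept_sp)
    _write_supermatrix(sm_sp, args.outdir / "supermatrix_species")
    print(f"species level: {len(kept_sp.genes)}/{len(species_ogs.genes)} genes "
          f"pass; supermatrix {sm_sp.alignment.length} nt, "
          f"{100 * sm_sp.completeness:.1f}% complete")

    rates = gene_rates(kept_sp)
    bins = bin_by_rate(rates, n_bins=min(args.n_bins, len(rates)))
    with open(args.outdir / "rate_bins.tsv", "w") as fh:
        fh.write("gene\trate\tbin\n")
        for gid in sorted(rates):
            r = rates[gid]
            fh.write(f"{gid}\t{'' if r is None else f'{r:.6f}'}\t{bins[gid]}\n")
    print(f"binned {len(rates)} genes into {max(bins.values()) + 1} rate bins")


if __name__ == "__main__":
    main()
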