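"""Generate the synthetic study inputs every later stage consumes.

Emulates, at desk scale, the inputs of a phylogenomic study of a
montane rodent radiation: per-gene CDS alignments for individual
samples (with planted quality defects), a time-calibrated species tree
with node-age credibility intervals, a geographic range coding over
four areas (H = the focal mountain region, Q = adjacent plateau,
M = monsoon lowlands, A = arid interior), species elevations evolved
under Brownian motion, and taxon groups for the gene-flow survey.

Writes everything as FASTA / Newick / TSV under results/inputs/.
"""

from __future__ import annotations

import argparse
from pathlib import Path

import numpy as np

from orodiversify.biogeography import GeoParams
from orodiversify.io_model import write_fasta, write_time_tree
from orodiversify.synthetic_data import (
    DECSimSpec,
    GeneFixtureSpec,
    make_orthogroup_fixtures,
    simulate_bm,
    simulate_dec_history,
    simulate_time_tree,
)

N_SPECIES = 30
N_GENES = 60
AREAS = ("H", "Q", "M", "A")
# rates chosen so a ~12 Ma radiation sees a handful of range shifts
GEO = GeoParams(d=0.05, e=0.02)
BM_SIGMA2 = 4.0e4  # m^2 / Ma
BM_ROOT_ELEV = 1500.0  # m


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/inputs"))
    args = ap.parse_args(argv)
    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(args.seed)

    # --- species tree (pure birth, ~12 Ma root) --------------------------
    tree = simulate_time_tree(N_SPECIES, birth_rate=0.28,
                              seed=int(rng.integers(2**31)))
    names = {f"t{i}": f"sp{i + 1:02d}" for i in range(N_SPECIES)}
    for tip in tree.tips():
        tip.id = names[tip.id]
    tree = type(tree)(tree.root)  # re-index under the new tip ids
    write_time_tree(tree, out / "species_tree.nwk")

    # --- range history on the tree ---------------------------------------
    hist = simulate_dec_history(
        DECSimSpec(areas=AREAS, params=GEO, tree=tree,
                   seed=int(rng.integers(2**31)))
    )
    with open(out / "areas.tsv", "w") as fh:
        fh.write("# areas: " + ",".join(AREAS) + "\n")
        fh.write("taxon\trange\n")
        for taxon in sorted(hist.coding.ranges):
            rng_str = "".join(a for a in AREAS if a in hist.coding.ranges[taxon])
            fh.write(f"{taxon}\t{rng_str}\n")

    # --- elevations under Brownian motion --------------------------------
    tips, _ = simulate_bm(tree, sigma2=BM_SIGMA2, root_value=BM_ROOT_ELEV,
                          seed=int(rng.integers(2**31)))
    with open(out / "elevation.tsv", "w") as fh:
        fh.write("taxon\televation\n")
        for taxon in sorted(tips):
            fh.write(f"{taxon}\t{tips[taxon]:.1f}\n")

    # --- per-gene alignments with planted defects ------------------------
    species = sorted(names.values())
    samples, smap = [], {}
    for sp in species:
        k = 2 if rng.random() < 0.4 else 1  # some species sampled twice
        for letter in "ab"[:k]:
            sid = f"{sp}_{letter}"
            samples.append(sid)
            smap[sid] = sp
    specs = []
    for _ in range(N_GENES):
        specs.append(
            GeneFixtureSpec(
                missing=float(rng.uniform(0.0, 0.8)),
                ambiguous=float(rng.choice([0.0, 0.0005, 0.002])),
                n_absent_taxa=int(rng.choice([0, 0, 0, 1, 4])),
            )
        )
    ogs, record = make_orthogroup_fixtures(
        specs, samples, length=300, seed=int(rng.integers(2**31)),
        groups=smap, divergence=0.001,
    )
    gene_dir = out / "orthogroups"
    gene_dir.mkdir(exist_ok=True)
    for gid, aln in ogs.genes.items():
        write_fasta(aln, gene_dir / f"{gid}.fasta")
    record.to_csv(out / "planted_gene_metrics.tsv", sep="\t")
    with open(out / "samples.tsv", "w") as fh:
        fh.write("sample\tspecies\n")
        for sid in samples:
            fh.write(f"{sid}\t{smap[sid]}\n")

    # --- groups for the gene-flow survey ----------------------------------
    # P1: focal-region radiation, P2: its widespread relatives, P3: the
    # other tribe; last species plays the outgroup
    with open(out / "groups.tsv", "w") as fh:
        fh.write("taxon\tgroup\n")
        for sp in species[0:8]:
            sub = "RichGenus" if sp in species[0:5] else "PoorGenus"
            fh.write(f"{sp}\tP1:{sub}\n")
        for sp in species[8:14]:
            fh.write(f"{sp}\tP2\n")
        for sp in species[14:22]:
            fh.write(f"{sp}\tP3\n")
        fh.write(f"{species[-1]}\toutgroup\n")

    print(f"wrote inputs for {N_SPECIES} species / {len(samples)} samples, "
          f"{N_GENES} genes, root age {tree.root.age:.2f} Ma -> {out}")


if __name__ == "__main__":
    main()
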