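#!/usr/bin/env python
"""Cofactor network and iron accounting on the toy complex.

Generates the toy structure, parses it back, extracts the cofactor
network with edge-to-edge distances, finds the cysteines ligating the
membrane [2Fe2S] cluster, traces the ET chain from the RnfB ladder to
AE1, and tabulates the iron bookkeeping for the deletion variants and
their measured relative activities.  Writes results/network_edges.csv and
results/structure_summary.json.

Finding: the full cofactor complement (10 [4Fe4S] + 1 [2Fe2S]) carries
42 Fe, matching the measured 41.8 ± 1.5 mol Fe/mol; removing AE1 or B8
loses 2 and 4 Fe while flavin deletions leave the iron untouched, and the
AE1 cluster is ligated by the conserved four-cysteine motif.
"""

import json
from pathlib import Path

from rnfpump import structure_cofactors as sc
from rnfpump import synthetic_data as syn

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    workdir = RESULTS / "toy_complex"
    _, manifest = syn.make_toy_complex(out_dir=workdir)
    atoms = sc.load_structure(workdir / "toy_complex.pdb")
    net = sc.build_network(atoms)
    net.distances.round(3).to_csv(RESULTS / "network_edges.csv")

    fmn_g = next(
        r.id for r in net.cofactors if r.kind == "FMN" and r.id.startswith("G")
    )
    chain = sc.build_et_chain(net, "B/SF4308", manifest["ae1_id"])

    variants = {
        "dAE1": sc.VariantSpec("dAE1", [manifest["ae1_id"]]),
        "dB8": sc.VariantSpec("dB8", [manifest["b8_id"]]),
        "dFMNG": sc.VariantSpec("dFMNG", [fmn_g]),
    }
    activities = {  # measured U/mg against the 7.1 U/mg wildtype
        "R67A": 0.7, "Y105A": 3.4, "L103G": 0.8,
    }

    summary = {
        "cofactor_counts": {
            k: sum(1 for r in net.cofactors if r.kind == k)
            for k in ("SF4", "FES", "FMN", "RBF")
        },
        "iron_inventory": sc.iron_inventory(net),
        "ae1_ligands": [
            list(t) for t in sc.cluster_ligands(net, manifest["ae1_id"])
        ],
        "b8_ae1_edge_A": round(
            float(net.distances.loc[manifest["b8_id"], manifest["ae1_id"]]), 2
        ),
        "chain_b1_to_ae1": chain.path,
        "variant_fe_deltas": {
            name: sc.variant_fe_delta(net, v) for name, v in variants.items()
        },
        "relative_activities_pct": {
            name: sc.relative_activity(u, 7.1)[1] for name, u in activities.items()
        },
    }
    (RESULTS / "structure_summary.json").write_text(
        json.dumps(summary, indent=2) + "\n"
    )
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
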