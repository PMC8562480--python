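#!/usr/bin/env python
"""Generate the synthetic studies every later stage analyses.

Writes two 20-sample community studies under the canonical assembly design
(one assembled neutrally, one by habitat filtering at 0.25 trait-SD) and
one 80-sample feature table with 40 features per response shape at SNR 4.
Everything downstream (02-05) reads these files, so the whole analysis is
reproducible from this single seeded step.
"""
import argparse
from pathlib import Path

from gutassembly import io as gio
from gutassembly import study

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out-dir", type=Path,
                        default=ROOT / "results" / "synthetic")
    args = parser.parse_args()

    for mode in ("neutral", "filtering"):
        out = args.out_dir / mode
        out.mkdir(parents=True, exist_ok=True)
        tree, traits, metadata, table = study.run_assembly_study(
            mode, seed=args.seed)
        gio.write_otu_table(table, out / "otu_table.tsv")
        gio.write_tree(tree, out / "tree.nwk")
        gio.write_metadata(metadata, out / "metadata.tsv")
        traits.to_frame().to_csv(out / "traits.tsv", sep="\t")
        print(f"[{mode}] {table.n_samples} samples x {table.n_otus} taxa "
              f"-> {out}")

    out = args.out_dir / "screen"
    out.mkdir(parents=True, exist_ok=True)
    metadata, features, truth = study.run_screen_study(n_per_shape=40,
                                                       seed=args.seed)
    gio.write_metadata(metadata, out / "metadata.tsv")
    features.to_csv(out / "features.tsv", sep="\t", index_label="#SampleID")
    truth.to_frame().to_csv(out / "truth.tsv", sep="\t",
                            index_label="feature")
    print(f"[screen] {features.shape[0]} samples x {features.shape[1]} "
          f"features -> {out}")


if __name__ == "__main__":
    main()
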