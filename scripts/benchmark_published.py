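#!/usr/bin/env python
"""Reproduce the published benchmark analyses against local model files.

Expects a directory holding the published *Chlorella ohadii* models (SBML),
e.g. iCO1515.xml (and optionally eciCO1515.xml / iCre1355.xml for the
cross-species comparisons), obtained from the authors' repository.  Nothing
is downloaded.  For each available analysis the script prints the computed
value next to the published reference:

  FBA growth per condition      1.711 / 1.459 / 3.71 / 3.03 1/h
  essential genes (auto_100)    237          essential reactions  670
  essential genes, all-condition intersection   168
  active-reaction partition     142 hetero-only, 25 hetero&mixo-only
  growth-correlated genes       514
  ecGEM growth ratio vs eciCre1355 (mixo chemostat)  41x

Usage:
  python scripts/benchmark_published.py --model-dir data/external \
      [--skip-essentiality] [--skip-targets]
"""

from __future__ import annotations

import argparse
from pathlib import Path

from algaegem import (
    call_active_reactions,
    condition_partition,
    essentiality,
    fba,
    growth_correlated_targets,
    read_model,
    standard_condition,
)

REFERENCE = {
    "auto_3k": 1.711, "auto_100": 1.459, "mixo": 3.71, "hetero": 3.03,
}


def find_model(model_dir: Path, stem: str):
    for suffix in (".xml", ".sbml", ".json"):
        path = model_dir / f"{stem}{suffix}"
        if path.exists():
            return read_model(path)
    return None


def pick_biomass(model, condition: str) -> str:
    for rid in (f"biomass_{condition}", "biomass"):
        if model.has_reaction(rid):
            return rid
    candidates = [r.id for r in model.reactions if "biomass" in r.id.lower()]
    matching = [c for c in candidates if condition in c]
    if matching:
        return matching[0]
    if candidates:
        return candidates[0]
    raise SystemExit(f"no biomass reaction found for condition {condition}")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--model-dir", type=Path, required=True)
    parser.add_argument("--skip-essentiality", action="store_true")
    parser.add_argument("--skip-targets", action="store_true")
    args = parser.parse_args()

    model = find_model(args.model_dir, "iCO1515")
    if model is None:
        raise SystemExit(
            f"iCO1515 model not found under {args.model_dir}; place the "
            "published SBML file there first"
        )
    print(f"loaded iCO1515: {len(model.reactions)} reactions, "
          f"{len(model.metabolites)} metabolites, {len(model.genes)} genes "
          "(published: 2516 reactions, 1515 genes)")

    conditions = {
        name: standard_condition(name, biomass_id=pick_biomass(model, name))
        for name in ("auto_100", "auto_3k", "mixo", "hetero")
    }

    print("\nFBA growth rates (computed vs published):")
    for name, cond in conditions.items():
        res = fba(model, cond)
        print(f"  {name:9s} {res.objective:7.3f} 1/h  (published {REFERENCE[name]})")

    print("\nActive-reaction partition across conditions:")
    active = {
        name: call_active_reactions(model, conditions[name])
        for name in ("auto_100", "mixo", "hetero")
    }
    part = condition_partition(active["auto_100"], active["mixo"], active["hetero"])
    print(f"  hetero-only      {len(part['hetero_only'])} (published 142)")
    print(f"  hetero&mixo-only {len(part['mixo_hetero'])} (published 25)")
    print(f"  auto-only        {len(part['auto_only'])} (published 71)")
    print(f"  mixo-only        {len(part['mixo_only'])} (published 76)")

    if not args.skip_essentiality:
        print("\nEssentiality under photoautotrophic low light:")
        ess_genes = essentiality(model, conditions["auto_100"], target="gene")
        ess_rxns = essentiality(model, conditions["auto_100"], target="reaction")
        print(f"  essential genes     {len(ess_genes)} (published 237)")
        print(f"  essential reactions {len(ess_rxns)} (published 670)")
        common = set(ess_genes)
        for name in ("auto_3k", "mixo", "hetero"):
            common &= essentiality(model, conditions[name], target="gene")
        print(f"  common to all conditions {len(common)} (published 168)")

    if not args.skip_targets:
        print("\nGrowth-correlated target screen (auto_100):")
        screen = growth_correlated_targets(model, conditions["auto_100"],
                                           n_increments=100, r_min=0.8, alpha=0.01)
        print(f"  correlated genes {len(screen.genes)} (published 514)")

    ec = find_model(args.model_dir, "eciCO1515")
    ec_ref = find_model(args.model_dir, "eciCre1355")
    if ec is not None and ec_ref is not None:
        print("\nEnzyme-constrained growth ratio (mixotrophic chemostat):")

        def chemostat_mixo(m):
            # acetate uptake 2.72, CO2 uptake 2 mmol/gDW/h, low light
            cond = standard_condition("mixo", biomass_id=pick_biomass(m, "mixo"))
            for rid, bounds in (("EX_ac", (-2.72, 0.0)), ("EX_co2", (-2.0, 1000.0))):
                if m.has_reaction(rid):
                    cond.bound_overrides[rid] = bounds
            return fba(m, cond).objective

        mu_co = chemostat_mixo(ec)
        mu_cre = chemostat_mixo(ec_ref)
        if mu_cre > 0:
            print(f"  eciCO1515/eciCre1355 = {mu_co / mu_cre:.1f}x (published 41x)")
    else:
        print("\n(enzyme-constrained models not found; skipping the 41x ratio)")


if __name__ == "__main__":
    main()
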