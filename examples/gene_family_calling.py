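"""Call gene-family members with the composite all-required-domains rule.

Builds a benchmark of five planted families (the ARF-like family requires
BOTH a B3 and an Auxin_resp domain) plus 1,000 background proteins, calls
members from the per-domain hit table, and scores the calls against the
planted truth.
"""

import tempfile

from genokit import fixtures, genefam

with tempfile.TemporaryDirectory() as tmp:
    fb = fixtures.make_family_benchmark(fixtures.FixtureSpec(seed=42), tmp)
    hits = genefam.parse_domtbl(fb.domtbl_path)
    print(f"{len(hits)} per-domain hits parsed\n")

    for fam in fb.families:
        definition = genefam.FamilyDefinition(
            fam.name, frozenset(fam.required_models)
        )  # defaults: e-value <= 1e-5, coverage > 0.80
        call = genefam.call_family_members(hits, definition)
        metrics = genefam.evaluate_precision_recall(
            call.members, fb.truth_positive[fam.name], fb.truth_negative
        )
        models = "+".join(sorted(fam.required_models))
        print(f"{fam.name:6s} ({models}): {len(call.members)} members, "
              f"TP={metrics.tp} FP={metrics.fp} FN={metrics.fn}, "
              f"precision={metrics.precision:.2f} recall={metrics.recall:.2f}")

# Precision and recall of 1.00 per family mean every planted member was
# recovered and no background protein slipped through — background proteins
# with only one of ARF's two domains, weak e-values, or shallow coverage are
# all rejected by the composite rule.
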