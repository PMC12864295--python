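"""Classify published colony trends against Stockholm Convention milestones.

Re-derives the trend-model label (IT / LI / NI / EI / CT / NS) for each of
the 68 published colony x HFR-class fits from the 2008-2023 herring gull
monitoring programs and tallies them.
"""

from hfrtrends.classify import load_reference_fits, tabulate

fits = load_reference_fits()
labelled, tallies = tabulate(fits)

agree = (labelled["assigned_label"].where(
    labelled["assigned_label"] != "NS", "") == labelled["label"]).mean()
print(f"comparisons:                 {tallies['total']}")
print(f"labels reproduced:           {agree:.0%}")
print(f"stable (no significant fit): {tallies['n_not_significant']} "
      f"({tallies['n_not_significant'] / tallies['total']:.0%})")
print(f"consistent declines:         {tallies['n_ct_declines']}")
print(f"declines by class:           {tallies['ct_declines_by_class']}")
print("labels:", "  ".join(f"{k}={v}" for k, v in tallies["labels"].items()))
print("\nThree quarters of colony series are stable; breakpoints aligned "
      "with nomination/listing windows are the exception, not the rule.")
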