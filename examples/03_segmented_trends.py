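"""Breakpoint (segmented) trend fitting on a single concentration series.

A colony's annual ln concentrations are modelled as two line segments
joined at an estimated breakpoint year; a straight line is kept instead
when the breakpoint does not significantly improve the description.
"""

import numpy as np

from hfrtrends.classify import percent_annual_change_rounded
from hfrtrends.segmented import select_trend_fit

rng = np.random.default_rng(3)
years = np.arange(2008, 2022)
truth = np.where(years <= 2015, 2.0 + 0.30 * (years - 2008),
                 2.0 + 0.30 * 7 - 0.20 * (years - 2015))
y = truth + rng.normal(0, 0.10, years.size)

fit = select_trend_fit(years, y)
print(f"fit type:        {fit.fit_type}   ({fit.selection_note})")
print(f"breakpoint year: {fit.psi:.1f} +- {fit.psi_se:.2f}")
print(f"slope before:    {fit.slope_before:+.3f} +- {fit.se_before:.3f} "
      f"ln-units/yr  (~{percent_annual_change_rounded(fit.slope_before)}%/yr)")
print(f"slope after:     {fit.slope_after:+.3f} +- {fit.se_after:.3f} "
      f"ln-units/yr  (~{percent_annual_change_rounded(fit.slope_after)}%/yr)")
print(f"t (first slope): {fit.t_value:.2f}, p = {fit.p_value:.4f}")
print(f"\nGenerating truth: breakpoint 2015, slopes +0.30/-0.20; the fit "
      f"estimates a ~{percent_annual_change_rounded(fit.slope_before)}%/yr "
      f"rise turning into a "
      f"~{percent_annual_change_rounded(fit.slope_after)}%/yr decline at "
      f"{fit.psi:.0f}. Slopes are per calendar year on the ln scale.")
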