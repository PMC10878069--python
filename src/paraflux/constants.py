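"""Named physiological constants used by the yield protocols.

The ATP-per-substrate coefficients are the model-predicted energetic yields
used to convert maintenance substrate consumption (Pirt intercepts) into a
maintenance ATP rate.  Two mannitol coefficients circulate in the source
material for this organism (29.1 vs 29.7 mol ATP mol^-1); both are kept as
named constants and the choice is always explicit at the call site.
"""

#: mmol per mol — the single place the yield unit conversion lives.
#: Y (g-DW mol^-1) = MMOL_PER_MOL * mu (h^-1) / q_s (mmol g-DW^-1 h^-1)
MMOL_PER_MOL = 1000.0

#: model-predicted ATP yield on methanol, mol ATP per mol substrate
METHANOL_ATP_PER_MOL = 4.9
#: model-predicted ATP yield on mannitol (value stated in the running text)
MANNITOL_ATP_PER_MOL = 29.7
#: mannitol coefficient as printed in the maintenance combination equation
MANNITOL_ATP_PER_MOL_EQ2 = 29.1

#: non-growth-associated ATP consumption used for batch simulations,
#: mmol ATP g-DW^-1 h^-1 (low end of the chemostat-derived interval)
MAINTENANCE_ATP_BATCH = 5.5
#: chemostat-derived maintenance ATP estimate and its standard deviation
MAINTENANCE_ATP_CHEMOSTAT = 7.5
MAINTENANCE_ATP_CHEMOSTAT_SD = 2.0
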