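{
 "description": "Independent oracle values for the AT+pH carbonate solve: the full three-unknown equilibrium system rooted numerically (scipy fsolve) in a separate scratch transcription of the constants, NOT the package's closed-form path.",
 "constants_check_values": {
  "comment": "published check values at t=25 C, S=35 (total scale)",
  "pK1": 5.8472,
  "pK2": 8.966,
  "lnKB": -19.7964,
  "lnKW": -30.434,
  "lnK0": -3.5617,
  "BT_mol_kg": 0.0004157
 },
 "cases": [
  {
   "at_umol_kg": 2300,
   "ph_total": 8.05,
   "temp_c": 16,
   "salinity": 35,
   "dic_umol_kg": 2071.9652,
   "pco2_uatm": 395.0391
  },
  {
   "at_umol_kg": 2300,
   "ph_total": 7.75,
   "temp_c": 16,
   "salinity": 35,
   "dic_umol_kg": 2198.2401,
   "pco2_uatm": 864.416
  },
  {
   "at_umol_kg": 2350,
   "ph_total": 8.1,
   "temp_c": 25,
   "salinity": 35,
   "dic_umol_kg": 2011.9644,
   "pco2_uatm": 346.7443
  },
  {
   "at_umol_kg": 2250,
   "ph_total": 7.9,
   "temp_c": 9,
   "salinity": 34,
   "dic_umol_kg": 2137.3094,
   "pco2_uatm": 567.6234
  },
  {
   "at_umol_kg": 2300,
   "ph_total": 8.0,
   "temp_c": 6,
   "salinity": 35,
   "dic_umol_kg": 2161.7466,
   "pco2_uatm": 442.6448
  },
  {
   "at_umol_kg": 2400,
   "ph_total": 8.2,
   "temp_c": 20,
   "salinity": 36,
   "dic_umol_kg": 2033.2138,
   "pco2_uatm": 267.2874
  },
  {
   "at_umol_kg": 2200,
   "ph_total": 7.7,
   "temp_c": 29,
   "salinity": 33,
   "dic_umol_kg": 2059.2685,
   "pco2_uatm": 977.188
  },
  {
   "at_umol_kg": 2300,
   "ph_total": 7.78,
   "temp_c": 16.69,
   "salinity": 35,
   "dic_umol_kg": 2183.6862,
   "pco2_uatm": 802.7317
  },
  {
   "at_umol_kg": 2320,
   "ph_total": 8.03,
   "temp_c": 12.82,
   "salinity": 34.5,
   "dic_umol_kg": 2126.4825,
   "pco2_uatm": 420.9483
  },
  {
   "at_umol_kg": 2280,
   "ph_total": 7.95,
   "temp_c": 22.59,
   "salinity": 35,
   "dic_umol_kg": 2053.5457,
   "pco2_uatm": 513.1142
  }
 ]
}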