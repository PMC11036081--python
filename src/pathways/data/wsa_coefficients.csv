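# Power-law wetted-surface-area regression coefficients: WSA = a * dim^b (m^2).
# input_dim is the predictor the row applies to: DWT (tonnes), BOA (m) or LOA (m).
# The values below are ILLUSTRATIVE editable defaults of plausible magnitude,
# not fitted regression estimates; replace this file with fitted values for
# production use.  The pipeline and all tests parameterise over this table.
category,input_dim,a,b
Bulk carrier,DWT,4.26,0.615
Cargo,DWT,5.00,0.580
Fishing,DWT,8.60,0.530
Fishing,BOA,9.57,1.680
Other,DWT,7.00,0.550
Other,LOA,0.77,1.520
Passenger,DWT,9.10,0.560
Passenger,BOA,7.80,1.750
Tanker,DWT,5.70,0.620
Tugs and supply,DWT,10.00,0.500
Tugs and supply,BOA,12.00,1.500
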