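name,mz,taxa,mass_class
COL1a1 508-519,1105.6,Bos;Bison;Ovibos;Ovis,low
COL1a2 978-990,1208.0,Bos;Bison;Ovibos,low
COL1a2 484-498,1427.7,Bos;Bison;Ovibos,low
COL1a2 454-483,2131.1,Bos;Bison;Ovibos,high
COL1a2 757-789,2853.4,Bos;Bison;Ovibos,high
COL1a2 793-816,2957.4,Bos;Bison,high
COL1a1 586-618,3093.5,Bos;Bison,high
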