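(D_tropicalis,(D_ananassae,((D_melanogaster,(D_simulans,D_sechellia,D_mauritiana)),(D_yakuba,D_teissieri))));
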