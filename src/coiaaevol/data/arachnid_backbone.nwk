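(Xiphosurida,((Araneae,(Amblypygi,(Uropygi,Schizomida))),Palpigradi,(Scorpiones,(Pseudoscorpiones,Solifugae)),(Opiliones,Ricinulei),((Holothyrida,(Ixodida,Mesostigmata),Opilioacarida),(Trombidiformes,Sarcoptiformes))));
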