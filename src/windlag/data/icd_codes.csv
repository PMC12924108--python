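version,prefix,category,subclass
10,X40,overdose,acute
10,X41,overdose,acute
10,X42,overdose,acute
10,X43,overdose,acute
10,X44,overdose,acute
10,X45,overdose,acute
10,X60,overdose,acute
10,X61,overdose,acute
10,X62,overdose,acute
10,X63,overdose,acute
10,X64,overdose,acute
10,X65,overdose,acute
10,X85,overdose,acute
10,Y10,overdose,acute
10,Y11,overdose,acute
10,Y12,overdose,acute
10,Y13,overdose,acute
10,Y14,overdose,acute
10,Y15,overdose,acute
10,F10,mental_behavioral,chronic
10,F11,mental_behavioral,chronic
10,F12,mental_behavioral,chronic
10,F13,mental_behavioral,chronic
10,F14,mental_behavioral,chronic
10,F15,mental_behavioral,chronic
10,F16,mental_behavioral,chronic
10,F17,mental_behavioral,chronic
10,F18,mental_behavioral,chronic
10,F19,mental_behavioral,chronic
10,K70,alcohol_induced,chronic
10,G312,alcohol_induced,chronic
10,G621,alcohol_induced,chronic
10,I426,alcohol_induced,chronic
10,K292,alcohol_induced,chronic
10,K852,alcohol_induced,chronic
10,K860,alcohol_induced,chronic
10,E244,alcohol_induced,chronic
10,R780,alcohol_induced,chronic
9,E850,overdose,acute
9,E851,overdose,acute
9,E852,overdose,acute
9,E853,overdose,acute
9,E854,overdose,acute
9,E855,overdose,acute
9,E856,overdose,acute
9,E857,overdose,acute
9,E858,overdose,acute
9,E860,overdose,acute
9,E861,overdose,acute
9,E862,overdose,acute
9,E950,overdose,acute
9,E9620,overdose,acute
9,E9800,overdose,acute
9,E9801,overdose,acute
9,E9802,overdose,acute
9,E9803,overdose,acute
9,E9804,overdose,acute
9,E9805,overdose,acute
9,291,mental_behavioral,chronic
9,292,mental_behavioral,chronic
9,303,mental_behavioral,chronic
9,304,mental_behavioral,chronic
9,305,mental_behavioral,chronic
9,5710,alcohol_induced,chronic
9,5711,alcohol_induced,chronic
9,5712,alcohol_induced,chronic
9,5713,alcohol_induced,chronic
9,4255,alcohol_induced,chronic
9,5353,alcohol_induced,chronic
9,5770,alcohol_induced,chronic
9,5771,alcohol_induced,chronic
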