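dose_mg_per_kg,time_h,mean_mM,sem_mM,n
192.0,0.0,0.17145291272587726,0.006839514708839458,8
192.0,0.25,0.3689696722896252,0.012574802758853374,8
192.0,0.5,0.9098866187356858,0.027109355313146146,8
192.0,0.75,1.3240188381021456,0.05813150896734662,8
192.0,1.0,1.4729143530056417,0.0586354100412588,8
192.0,1.5,1.3577717630847643,0.04875493655764643,8
192.0,2.0,1.242037473570727,0.02271092848428853,8
192.0,3.0,1.0937674789402667,0.03435402291973797,8
192.0,4.0,0.8669526114303681,0.027382075722005392,8
192.0,6.0,0.43528642115583804,0.007946720449387976,8
573.0,0.0,0.16255019193180328,0.00776690767467272,8
573.0,0.25,0.8118590777963846,0.021367687474725682,8
573.0,0.5,2.371665166020956,0.05220472165879199,8
573.0,0.75,3.938513719748017,0.23367409788743618,8
573.0,1.0,4.989084037970887,0.15189096456514084,8
573.0,1.5,5.540183987559052,0.18619952923078376,8
573.0,2.0,5.449470833333185,0.24351825925518594,8
573.0,3.0,5.157054597637597,0.15131958112995844,8
573.0,4.0,3.5540921919055894,0.10171833455388678,8
573.0,6.0,1.1835573272080604,0.030282529481933912,8
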